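order,common_name,species,pigment_class,pigment_lambda_max,lambda_t50,axial_length_mm,group_label,notes
Psittaciformes,Bourke's parrot,Neopsephotus bourkii,UVS,,334,,parrot,pigment type inferred from phylogeny
Psittaciformes,budgerigar,Melopsittacus undulatus,UVS,371,320,,parrot,
Psittaciformes,crimson rosella,Platycercus elegans,UVS,363,319,,parrot,
Passeriformes,common starling,Sturnus vulgaris,UVS,362,337,,UVS-passerine,OMT averaged from separately measured ocular components
Passeriformes,common blue tit,Cyanistes caeruleus,UVS,372,316,,UVS-passerine,
Passeriformes,great tit,Parus major,UVS,,314,,UVS-passerine,pigment type inferred from phylogeny
Passeriformes,common blackbird,Turdus merula,UVS,373,343,,UVS-passerine,
Passeriformes,song thrush,Turdus philomelos,UVS,,335,,UVS-passerine,pigment type inferred from phylogeny
Passeriformes,Gouldian finch,Erythrura gouldiae,UVS,370,315,,UVS-passerine,
Passeriformes,cut-throat finch,Amadina fasciata,UVS,370,316,,UVS-passerine,
Passeriformes,white-headed munia,Lonchura maja,UVS,373,317,,UVS-passerine,
Passeriformes,plum-headed finch,Neochmia modesta,UVS,373,314,,UVS-passerine,
Passeriformes,Timor zebra finch,Taeniopygia guttata,UVS,359,321,,UVS-passerine,
Passeriformes,rook,Corvus frugilegus,VS,,365,,VS-passerine,pigment type inferred from phylogeny
Passeriformes,common magpie,Pica pica,VS,,370,,VS-passerine,pigment type inferred from phylogeny
Passeriformes,green catbird,Ailuroedus crassirostris,VS,406,340,,VS-passerine,
Passeriformes,great bowerbird,Chlamydera nuchalis,VS,404,349,,VS-passerine,
Passeriformes,regent bowerbird,Sericulus chrysocephalus,VS,408,349,,VS-passerine,
Passeriformes,satin bowerbird,Ptilonorhynchus violaceus,VS,410,344,,VS-passerine,
Passeriformes,spotted bowerbird,Chlamydera maculata,VS,,351,,VS-passerine,
Strigiformes,burrowing owl,Athene cunicularia,VS,,359,,owl,VS grouping uncertain: no sws1 pigment found in owls
Strigiformes,northern long-eared owl,Asio otus,VS,,356,,owl,VS grouping uncertain: no sws1 pigment found in owls
Strigiformes,tawny owl,Strix aluco,VS,,353,,owl,VS grouping uncertain: no sws1 pigment found in owls
Strigiformes,boreal owl,Aegolius funereus,VS,,335,,owl,VS grouping uncertain: no sws1 pigment found in owls
Falconiformes,Eurasian buzzard,Buteo buteo,VS,405,375,,raptor,
Falconiformes,Eurasian sparrowhawk,Accipiter nisus,VS,405,369,,raptor,
Falconiformes,red kite,Milvus milvus,VS,,394,,raptor,pigment type inferred from phylogeny
Falconiformes,common kestrel,Falco tinnunculus,VS,,379,,raptor,pigment type inferred from phylogeny
Struthioniformes,ostrich,Struthio camelus,VS,405,369,,other,OMT unknown at very short wavelengths
Galliformes,domestic chicken,Gallus gallus domesticus,VS,418,351,,landfowl,
Galliformes,wild turkey,Meleagris gallopavo,VS,420,355,,landfowl,
Galliformes,Indian peafowl,Pavo cristatus,VS,421,364,,landfowl,
Apodiformes,common swift,Apus apus,VS,,388,,other,pigment type inferred from phylogeny
Apodiformes,green-backed firecrown,Sephanoides sephaniodes,VS,,310,,other,pigment type inferred from phylogeny
Columbiformes,rock dove,Columba livia,VS,404,337,,other,
Procellariiformes,wedge-tailed shearwater,Puffinus pacificus,VS,406,335,,other,
Podicipediformes,great crested grebe,Podiceps cristatus,VS,,390,,other,
Anseriformes,mallard,Anas platyrhynchos,VS,420,371,,other,OMT unknown at very short wavelengths
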