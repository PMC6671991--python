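field,raw,canonical
agency,usace,Army Corps of Engineers
agency,u.s. army corps of engineers,Army Corps of Engineers
agency,army corps,Army Corps of Engineers
agency,corps of engineers,Army Corps of Engineers
agency,usfs,Forest Service
agency,u.s. forest service,Forest Service
agency,nmfs,National Marine Fisheries Service
agency,noaa fisheries,National Marine Fisheries Service
agency,fema,Federal Emergency Management Agency
agency,blm,Bureau of Land Management
agency,epa,Environmental Protection Agency
agency,u.s. environmental protection agency,Environmental Protection Agency
agency,ferc,Federal Energy Regulatory Commission
agency,uscg,Coast Guard
agency,u.s. coast guard,Coast Guard
agency,nps,National Park Service
agency,us navy,Navy
agency,department of the navy,Navy
work_type,water way,waterway
work_type,waterways,waterway
work_type,fisheries,fishery
work_type,fishery management,fishery
work_type,transport,transportation
work_type,ag,agriculture
work_type,agricultural,agriculture
work_type,develop,development
work_type,forest management,forestry
work_type,utilities,utility
work_type,ocean work,ocean
work_type,scientific research,research
work_type,military activities,military
species,chinook,Chinook salmon
species,oncorhynchus tshawytscha,Chinook salmon
species,steelhead trout,Steelhead
species,oncorhynchus mykiss,Steelhead
species,coho,Coho salmon
species,oncorhynchus kisutch,Coho salmon
species,sockeye,Sockeye salmon
species,oncorhynchus nerka,Sockeye salmon
species,chum,Chum salmon
species,oncorhynchus keta,Chum salmon
species,green turtle,Green sea turtle
species,chelonia mydas,Green sea turtle
species,loggerhead,Loggerhead sea turtle
species,caretta caretta,Loggerhead sea turtle
species,leatherback,Leatherback sea turtle
species,dermochelys coriacea,Leatherback sea turtle
species,orca,Killer whale
species,orcinus orca,Killer whale
species,right whale,North Atlantic right whale
species,eubalaena glacialis,North Atlantic right whale
species,acipenser medirostris,Green sturgeon
species,thaleichthys pacificus,Eulachon
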