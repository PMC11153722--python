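{
  "habitats": [
    "conserved forest",
    "lowland dipterocarp forest",
    "lowland mixed dipterocarp forests",
    "peat swamp forest",
    "montane forest",
    "riverine forest",
    "heath forest",
    "oak savanna",
    "logged - over forest",
    "coastal hill forest"
  ],
  "locations": [
    "Dongmakhai",
    "Bukit Sai",
    "Lesong",
    "Pasoh",
    "Kepong",
    "Gombak",
    "Ampang",
    "Borneo",
    "peninsular Malaysia",
    "Danum Valley",
    "Sarawak",
    "Lambir Hills"
  ],
  "reproductive_conditions": [
    "flowering",
    "fruiting",
    "mass flowering",
    "flowerings",
    "budburst",
    "seed fall",
    "fruit set",
    "sterility",
    "general flowering",
    "masting"
  ],
  "temporal_expressions": [
    "March",
    "April",
    "May",
    "June",
    "July",
    "August 1963",
    "May 1968",
    "October 2001",
    "December 2001",
    "February 2002",
    "September 2002",
    "August 2005",
    "1983",
    "1998",
    "end of July",
    "mid - August"
  ],
  "location_fillers": [
    "was recorded in the",
    "occurred across the",
    "dominates the slopes of",
    "was surveyed near"
  ],
  "negative_tails": [
    "was not recorded",
    "remained absent",
    "was not observed"
  ]
}
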