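feed_id,tdn_1x,tdn_3x,me_3x,note
Discarded corn,67.5,63.8,2.4,
Discarded sorghum,63.6,61.3,2.2,
Discarded sesame,53.5,53.5,1.9,"TDN_3X cell published as ""535""; decimal point restored"
Citrus pulp,84.0,74.4,2.8,
"Sugar cane, whole plant, 6 months",52.1,52.1,1.8,
Forage sorghum,45.6,45.6,1.5,
Bermudagrass,39.8,39.8,1.3,
Brachiaria,42.6,42.6,1.4,
King grass,42.1,42.1,1.4,
Kikuyu grass,41.5,41.5,1.4,
Guinea grass,60.7,59.4,2.2,
"Stargrass, 20 days",70.7,65.9,2.5,
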