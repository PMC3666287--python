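feed_id,LSdNDF,IVdNDF_075,IVdNDF,ISdNDF,RochaJunior,note
Discarded corn,57.7,58.8,67.5,70.2,58.3,
Discarded sorghum,62.7,59.3,63.6,69.6,63.8,Rocha-Junior cell published as "638"; decimal point restored
Discarded sesame,61.7,53.1,53.5,59.2,62.8,
Citrus pulp,71.3,78.8,84.0,87.0,72.4,
"Sugar cane, whole plant, 6 months",56.8,45.4,52.1,56.9,56.9,
Forage sorghum,48.3,38.9,45.6,47.6,49.4,
Bermudagrass,46.7,31.7,39.8,46.6,46.1,
Brachiaria,49.6,35.5,42.6,50.0,50.2,
King grass,52.5,35.1,42.1,48.0,51.7,
Kikuyu grass,41.6,32.9,41.5,47.3,42.0,
Guinea grass,45.2,48.9,60.7,61.5,45.9,
"Stargrass, 20 days",52.2,57.9,70.7,68.6,52.0,
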