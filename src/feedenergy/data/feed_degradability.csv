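feed_id,ivtdmd_48,ivtdmd_72,ivndfd_48,ivndfd_72,isdmd_48,isndfd_48,note
Discarded corn,77.4,81.6,60.6,67.9,65.5,65.3,
Discarded sorghum,73.2,79.1,39.0,52.5,67.3,52.6,
Discarded sesame,68.1,70.3,4.8,9.5,57.0,22.1,
Citrus pulp,94.9,96.6,80.5,86.9,96.4,92.0,
"Sugar cane, whole plant, 6 months",62.8,67.4,41.8,49.0,58.4,49.3,in situ cells published as 47.1/42.1; row-rotation corrected
Forage sorghum,58.2,65.5,39.3,50.0,47.1,42.1,in situ cells published as 47.5/50.1; row-rotation corrected
Bermudagrass,54.3,62.4,41.4,51.7,47.5,50.1,in situ cells published as 45.9/46.6; row-rotation corrected
Brachiaria,51.4,59.1,36.9,46.8,45.9,46.6,in situ cells published as 58.4/49.3; row-rotation corrected
King grass,54.7,62.2,38.0,48.3,46.0,46.1,
Kikuyu grass,61.0,65.1,46.7,52.4,49.1,54.6,
Guinea grass,75.2,80.8,65.6,73.4,64.5,66.8,
"Stargrass, 20 days",80.8,85.9,72.8,80.1,67.7,69.8,
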