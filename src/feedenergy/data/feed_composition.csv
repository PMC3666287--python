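feed_id,feed_class,dm,cp,ee,ndf,adf,lignin,ndicp,adicp,nfc,ash,fap,note
Discarded corn,concentrate,92.4,10.3,2.4,57.3,21.0,6.7,5.8,3.3,28.2,7.6,1.0,
Discarded sorghum,concentrate,93.1,7.9,2.2,43.9,23.1,6.8,5.5,2.1,44.5,7.0,1.0,
Discarded sesame,concentrate,73.7,5.2,13.6,32.8,50.8,6.8,4.9,2.6,26.9,26.4,1.0,ADF exceeds NDF as published
Citrus pulp,concentrate,94.9,6.1,3.1,25.9,28.9,6.4,1.2,1.3,61.0,5.1,1.0,
"Sugar cane, whole plant, 6 months",forage,96.3,4.3,0.8,63.9,38.6,6.5,3.2,2.0,30.5,3.7,1.0,
Forage sorghum,forage,93.1,5.3,0.9,68.9,46.4,9.0,5.5,3.3,23.5,6.9,1.0,
Bermudagrass,forage,90.3,8.0,1.0,77.9,46.5,6.6,6.0,2.6,9.3,9.8,1.0,
Brachiaria,forage,95.8,7.1,1.6,77.0,41.9,8.7,5.7,2.9,15.8,4.2,1.0,
King grass,forage,93.1,5.8,1.6,73.0,47.0,5.9,3.9,2.2,16.7,6.8,1.0,
Kikuyu grass,forage,85.2,7.4,0.8,73.2,42.8,7.8,5.4,2.0,9.1,14.9,1.0,
Guinea grass,forage,87.1,12.7,1.9,71.6,46.3,8.3,7.1,1.7,8.0,12.9,1.0,
"Stargrass, 20 days",forage,90.8,17.7,1.4,70.5,40.0,6.1,8.8,1.8,9.9,9.3,1.0,
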