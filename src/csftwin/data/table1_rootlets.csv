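# Spinal nerve rootlet records for the NHP model, one row per level per side.
# z_mm is the attachment position in mm caudal of the foramen magnum.
# provenance: "table" = read directly; "table-parsed" = digit grouping in the
# printed cell is ambiguous (diameter/count run together); parsed as diameter
# 0.4 mm with count 5, consistent with the 0.35->0.4->0.45 cervical progression.
level,side,z_mm,descending_angle_deg,radicular_line_mm,diameter_mm,count,provenance
C1,dorsal,3.6,4.6,3.0,0.35,4,table
C1,ventral,3.6,5.1,3.2,0.35,3,table
C2,dorsal,7.6,5.9,2.7,0.35,4,table
C2,ventral,7.6,6.2,4.0,0.35,4,table
C3,dorsal,12.5,35.9,4.5,0.35,6,table
C3,ventral,12.5,28.3,4.9,0.35,5,table
C4,dorsal,19.8,40.4,3.9,0.4,5,table-parsed
C4,ventral,19.8,37.0,3.6,0.4,5,table-parsed
C5,dorsal,26.0,37.8,3.3,0.4,5,table-parsed
C5,ventral,26.0,37.3,3.1,0.4,5,table-parsed
C6,dorsal,31.1,55.2,4.8,0.45,4,table
C6,ventral,31.1,39.5,5.1,0.45,4,table
C7,dorsal,36.5,71.5,2.9,0.5,4,table
C7,ventral,36.5,59.6,3.0,0.5,4,table
C8,dorsal,44.4,67.2,1.6,0.45,2,table
C8,ventral,44.4,58.6,1.9,0.45,2,table
T1,dorsal,50.7,68.0,3.2,0.55,3,table
T1,ventral,50.7,64.3,3.3,0.55,3,table
T2,dorsal,59.1,70.3,2.7,0.55,2,table
T2,ventral,59.1,69.9,2.7,0.55,2,table
T3,dorsal,69.3,75.0,3.9,0.55,2,table
T3,ventral,69.3,68.6,4.0,0.55,2,table
T4,dorsal,77.6,68.5,4.2,0.55,2,table
T4,ventral,77.6,65.8,4.1,0.55,2,table
T5,dorsal,81.8,74.4,3.3,0.55,2,table
T5,ventral,81.8,73.1,3.0,0.55,2,table
T6,dorsal,93.7,76.1,3.2,0.55,2,table
T6,ventral,93.7,76.2,3.3,0.55,2,table
T7,dorsal,100.3,79.5,4.3,0.55,2,table
T7,ventral,100.3,78.7,4.3,0.55,2,table
T8,dorsal,109.1,71.3,3.9,0.55,2,table
T8,ventral,109.1,79.8,3.8,0.55,2,table
T9,dorsal,118.4,79.9,3.3,0.55,2,table
T9,ventral,118.4,79.7,3.0,0.55,2,table
T10,dorsal,130.4,78.6,4.3,0.55,2,table
T10,ventral,130.4,77.7,6.0,0.55,2,table
T11,dorsal,147.3,79.8,9.5,0.55,2,table
T11,ventral,147.3,77.4,10.0,0.55,2,table
T12,dorsal,166.3,75.7,4.2,0.55,1,table
T12,ventral,166.3,74.8,4.1,0.55,1,table
L1,dorsal,181.3,74.6,4.8,0.55,1,table
L1,ventral,181.3,82.6,4.5,0.55,1,table
L2,dorsal,193.5,77.0,2.8,0.55,1,table
L2,ventral,193.5,85.1,3.0,0.55,1,table
L3,dorsal,208.8,87.1,2.0,0.75,1,table
L3,ventral,208.8,88.0,2.0,0.75,1,table
L4,dorsal,214.1,87.0,0.7,0.65,1,table
L4,ventral,214.1,87.6,0.7,0.65,1,table
L5,dorsal,218.9,87.3,0.6,0.6,1,table
L5,ventral,218.9,86.9,0.6,0.6,1,table
S1,dorsal,221.2,86.9,0.5,0.5,1,table
S1,ventral,221.2,87.0,0.5,0.5,1,table
S2,dorsal,224.7,86.6,0.3,0.25,1,table
S2,ventral,224.7,87.5,0.3,0.25,1,table
S3,dorsal,230.8,86.6,0.3,0.25,1,table
S3,ventral,230.8,87.0,0.3,0.25,1,table
S4,dorsal,230.8,86.8,0.3,0.25,1,table
S4,ventral,230.8,87.3,0.3,0.25,1,table
S5,dorsal,230.8,87.3,0.3,0.25,1,table
S5,ventral,230.8,87.5,0.3,0.25,1,table
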