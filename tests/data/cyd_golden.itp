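; dsbredox perturbed topology dialect v1
[ hybrid CYD 1 ]
[ meta thiol_h HG1 sulfur SG cb CB ]
[ atoms ]
; name typeA chargeA massA typeB chargeB massB flag
C C 0.51 12.011 C 0.51 12.011 -
CA CT1 0.07 12.011 CT1 0.07 12.011 -
CB CT2 -0.1 12.011 CT2 -0.11 12.011 -
HA HB 0.09 1.008 HB 0.09 1.008 -
HB1 HA 0.09 1.008 HA 0.09 1.008 -
HB2 HA 0.09 1.008 HA 0.09 1.008 -
HN H 0.31 1.008 H 0.31 1.008 -
N NH1 -0.47 14.007 NH1 -0.47 14.007 -
O O -0.51 15.999 O -0.51 15.999 -
SG S -0.08 32.06 S -0.23 32.06 -
HUD DUM 0.0 1.008 HS 0.16 1.008 dummyA
VC DUM 0.0 0.0 DUM 0.0 0.0 vsite=CB
VS DUM 0.0 0.0 DUM 0.0 0.0 vsite=SG
[ bonds ]
C CA AB
C O AB
CA CB AB
CA HA AB
CA N AB
CB HB1 AB
CB HB2 AB
CB SG AB
HN N AB
HUD SG B
[ angles ]
C CA CB AB
C CA HA AB
C CA N AB
CA C O AB
CA CB HB1 AB
CA CB HB2 AB
CA CB SG AB
CA N HN AB
CB CA HA AB
CB CA N AB
CB SG HUD B
HA CA N AB
HB1 CB HB2 AB
HB1 CB SG AB
HB2 CB SG AB
[ dihedrals ]
C CA CB HB1 AB
C CA CB HB2 AB
C CA CB SG AB
C CA N HN AB
CA CB SG HUD B
CB CA C O AB
CB CA N HN AB
HA CA C O AB
HA CA CB HB1 AB
HA CA CB HB2 AB
HA CA CB SG AB
HA CA N HN AB
HB1 CB CA N AB
HB1 CB SG HUD B
HB2 CB CA N AB
HB2 CB SG HUD B
N CA C O AB
N CA CB SG AB
[ hybrid CYD 2 ]
[ meta thiol_h HG1 sulfur SG cb CB ]
[ atoms ]
; name typeA chargeA massA typeB chargeB massB flag
C C 0.51 12.011 C 0.51 12.011 -
CA CT1 0.07 12.011 CT1 0.07 12.011 -
CB CT2 -0.1 12.011 CT2 -0.11 12.011 -
HA HB 0.09 1.008 HB 0.09 1.008 -
HB1 HA 0.09 1.008 HA 0.09 1.008 -
HB2 HA 0.09 1.008 HA 0.09 1.008 -
HN H 0.31 1.008 H 0.31 1.008 -
N NH1 -0.47 14.007 NH1 -0.47 14.007 -
O O -0.51 15.999 O -0.51 15.999 -
SG S -0.08 32.06 S -0.23 32.06 -
HUD DUM 0.0 1.008 HS 0.16 1.008 dummyA
VC DUM 0.0 0.0 DUM 0.0 0.0 vsite=CB
VS DUM 0.0 0.0 DUM 0.0 0.0 vsite=SG
[ bonds ]
C CA AB
C O AB
CA CB AB
CA HA AB
CA N AB
CB HB1 AB
CB HB2 AB
CB SG AB
HN N AB
HUD SG B
[ angles ]
C CA CB AB
C CA HA AB
C CA N AB
CA C O AB
CA CB HB1 AB
CA CB HB2 AB
CA CB SG AB
CA N HN AB
CB CA HA AB
CB CA N AB
CB SG HUD B
HA CA N AB
HB1 CB HB2 AB
HB1 CB SG AB
HB2 CB SG AB
[ dihedrals ]
C CA CB HB1 AB
C CA CB HB2 AB
C CA CB SG AB
C CA N HN AB
CA CB SG HUD B
CB CA C O AB
CB CA N HN AB
HA CA C O AB
HA CA CB HB1 AB
HA CA CB HB2 AB
HA CA CB SG AB
HA CA N HN AB
HB1 CB CA N AB
HB1 CB SG HUD B
HB2 CB CA N AB
HB2 CB SG HUD B
N CA C O AB
N CA CB SG AB
[ cross 1 2 ]
bond 1:SG 2:SG A
angle 1:CB 1:SG 2:SG A
angle 2:CB 2:SG 1:SG A
dihedral 1:CB 1:SG 2:SG 2:CB A
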