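study,year,modality,orientation,boundary_condition,modulus_kind,n,mean_MPa,sd_MPa,linearity,note
green,1993,uniaxial,axial,vertebrae_attached,linear,9,16.4,7.0,NL,listed axial; modulus labeled Linear_circ in the source table
acaroglu,1995,uniaxial,circumferential,gripped,linear,15,27.0,15.0,NL,
elliott_setton,2001,uniaxial,axial,gripped,toe,12,0.27,0.28,PL,
elliott_setton,2001,uniaxial,axial,gripped,linear,12,0.82,0.71,PL,
elliott_setton,2001,uniaxial,circumferential,gripped,toe,20,2.52,2.27,NL,
elliott_setton,2001,uniaxial,circumferential,gripped,linear,20,17.45,14.29,NL,
guerin_elliott,2006,uniaxial,circumferential,gripped,toe,8,2.53,1.47,NL,
guerin_elliott,2006,uniaxial,circumferential,gripped,linear,8,29.35,21.92,NL,
oconnell,2009,uniaxial,axial,gripped,linear,7,0.42,0.11,PL,
oconnell,2009,uniaxial,circumferential,gripped,toe,7,2.70,2.33,NL,
oconnell,2009,uniaxial,circumferential,gripped,linear,7,20.90,13.50,NL,
zak_pezowicz,2013,uniaxial,axial,vertebrae_attached,linear,18,21.96,12.77,NL,
oconnell,2012,biaxial,circumferential,gripped,apparent_equibiaxial,16,60.0,,NL,representative curve value (~60 MPa); no SD reported
oconnell,2012,biaxial,axial,gripped,apparent_equibiaxial,16,30.0,,NL,representative curve value (~30 MPa); no SD reported
oconnell,2012,biaxial,circumferential,gripped,apparent_axial_fixed,16,40.0,,NL,representative curve value (~40 MPa); no SD reported
fujita,2000,shear,circumferential,parallel_plate,shear,20,0.111,0.056,,
fujita,2000,shear,axial,parallel_plate,shear,20,0.224,0.112,,
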