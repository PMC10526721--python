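region_a,region_b,type,pathway,era,publication,page,table,figure,tracer,species,notes
F2,AG,3,SLF,pre_dti,dejerine1901,,,,,human,in-paper: worked-example connection vector (long-range via SLF)
F2,SPL,3,SLF,pre_dti,dejerine1901,,,,,human,in-paper: F2 era-difference exemplar
F2,OLi,3,OFF,pre_dti,dejerine1901,,,,,human,in-paper: F2 era-difference exemplar
F2,PT,3,SLF,pre_dti,dejerine1901,,,,,human,in-paper: F2 era-difference exemplar
F2,CO,3,SLF,pre_dti,dejerine1901,,,,,human,in-paper: F2 era-difference exemplar
F2,PO,3,SLF,pre_dti,dejerine1901,,,,,human,in-paper: F2 era-difference exemplar
F2,CGp,3,CB,pre_dti,dejerine1901,,,,,human,in-paper: F2 era-difference exemplar
AG,F3o,3,SLF,pre_dti,dejerine1901,,,,,human,in-paper: AG era-difference exemplar
AG,CO,3,SLF,pre_dti,dejerine1901,,,,,human,in-paper: AG era-difference exemplar
AG,SMC,3,SLF,pre_dti,dejerine1901,,,,,human,in-paper: AG era-difference exemplar
AG,PHa,3,ILF,pre_dti,dejerine1901,,,,,human,in-paper: AG era-difference exemplar
F2,SGa,3,SLF,pre_dti,dejerine1901,,,,,human,"figure-level, unverified"
F2,SGp,3,SLF,pre_dti,dejerine1901,,,,,human,"figure-level, unverified"
F2,T1p,3,SLF,pre_dti,ludwig_klingler1956,,,,,human,"figure-level, unverified"
AG,F1,3,SLF,pre_dti,dejerine1901,,,,,human,"figure-level, unverified"
AG,F3t,3,SLF,pre_dti,dejerine1901,,,,,human,"figure-level, unverified"
AG,T1p,3,SLF,pre_dti,ludwig_klingler1956,,,,,human,"figure-level, unverified"
AG,OLi,3,ILF,pre_dti,dejerine1901,,,,,human,"figure-level, unverified"
AG,CGp,3,CB,pre_dti,dejerine1901,,,,,human,"figure-level, unverified"
F1,OLs,3,OFF,pre_dti,dejerine1901,,,,,human,"figure-level, unverified"
FOC,TP,3,UF,pre_dti,ludwig_klingler1956,,,,,human,"figure-level, unverified"
FOC,T1a,3,UF,pre_dti,ludwig_klingler1956,,,,,human,"figure-level, unverified"
F3o,T1a,3,EmC,pre_dti,ludwig_klingler1956,,,,,human,"figure-level, unverified"
OP,TP,3,ILF,pre_dti,dejerine1901,,,,,human,"figure-level, unverified"
AG,SGp,1,,pre_dti,makris1999,,,,,human,"figure-level, unverified"
AG,OLs,1,,pre_dti,makris1999,,,,,human,"figure-level, unverified"
AG,POG,2,,pre_dti,makris1999,,,,,human,"figure-level, unverified"
AG,PCN,2,,pre_dti,makris1999,,,,,human,"figure-level, unverified"
F2,F1,1,,pre_dti,makris1999,,,,,human,"figure-level, unverified"
F2,F3t,1,,pre_dti,makris1999,,,,,human,"figure-level, unverified"
F2,PRG,1,,pre_dti,makris1999,,,,,human,"figure-level, unverified"
F2,FP,1,,pre_dti,makris1999,,,,,human,"figure-level, unverified"
F2,FOC,2,,pre_dti,makris1999,,,,,human,"figure-level, unverified"
F2,FMC,2,,pre_dti,makris1999,,,,,human,"figure-level, unverified"
F2,La,4,IC,pre_dti,makris1999,,,,,human,"figure-level, unverified"
F2,A,4,IC,pre_dti,makris1999,,,,,human,"figure-level, unverified"
AG,Lp,4,IC,pre_dti,makris1999,,,,,human,"figure-level, unverified"
AG,P,4,IC,pre_dti,makris1999,,,,,human,"figure-level, unverified"
F2,PON,4,corticopontine,pre_dti,dejerine1901,,,,,human,"figure-level, unverified"
AG,PON,4,corticopontine,pre_dti,dejerine1901,,,,,human,"figure-level, unverified"
PRG,PON,4,corticopontine,pre_dti,dejerine1901,,,,,human,"figure-level, unverified"
F2,STR,4,corticostriatal,pre_dti,makris1999,,,,,human,"figure-level, unverified"
AG,STR,4,corticostriatal,pre_dti,makris1999,,,,,human,"figure-level, unverified"
F1,STR,4,corticostriatal,pre_dti,makris1999,,,,,human,"figure-level, unverified"
FOC,AMY,4,amygdalofugal,pre_dti,makris1999,,,,,human,"figure-level, unverified"
TP,AMY,4,amygdalofugal,pre_dti,makris1999,,,,,human,"figure-level, unverified"
PHa,HIP,4,,pre_dti,makris1999,,,,,human,"figure-level, unverified"
CALC,LGN,4,IC,pre_dti,dejerine1895,,,,,human,"figure-level, unverified"
H1,MGN,4,IC,pre_dti,dejerine1895,,,,,human,"figure-level, unverified"
POG,Lp,4,IC,pre_dti,dejerine1895,,,,,human,"figure-level, unverified"
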