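region_a,region_b,type,pathway,era,publication,page,table,figure,tracer,species,notes
F2,AG,3,SLF,dti,makris2005,,,,,human,"figure-level, unverified"
F2,SGa,3,SLF,dti,makris2005,,,,,human,"figure-level, unverified"
F2,SGp,3,SLF,dti,makris2005,,,,,human,"figure-level, unverified"
F2,T1p,3,SLF,dti,schmahmann2006,,,,autoradiography,macaque,"figure-level, unverified"
AG,F1,3,SLF,dti,makris2005,,,,,human,"figure-level, unverified"
AG,F3t,3,SLF,dti,makris2005,,,,,human,"figure-level, unverified"
AG,T1p,3,SLF,dti,schmahmann2006,,,,autoradiography,macaque,"figure-level, unverified"
AG,OLi,3,ILF,dti,makris2005,,,,,human,"figure-level, unverified"
AG,CGp,3,CB,dti,schmahmann2006,,,,autoradiography,macaque,"figure-level, unverified"
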