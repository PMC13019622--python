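&FCI NORB=2,NELEC=2,MS2=0,
 ORBSYM=1,1,
 ISYM=1,
&END
 6.7448876635683774E-01    1    1    1    1
 1.8128880821149584E-01    2    1    2    1
 6.6346809642356774E-01    2    2    1    1
 6.9739376742302661E-01    2    2    2    2
-1.2524635735648981E+00    1    1    0    0
-4.7594871522096421E-01    2    2    0    0
 7.1375399368761816E-01    0    0    0    0
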