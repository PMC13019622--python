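&FCI NORB=2,NELEC=2,MS2=0,
 ORBSYM=1,1,
 ISYM=1,
&END
 1.0269071688759450E+00    1    1    1    1
-3.1649047035049854E-01    2    1    1    1
 2.2767049526675942E-01    2    1    2    1
 8.5813333443740469E-01    2    2    1    1
-2.5555354578324657E-01    2    2    2    1
 7.6636289621173703E-01    2    2    2    2
-1.9410337975151948E+00    1    1    0    0
 3.1649047035132138E-01    2    1    0    0
-8.8736838353742756E-02    2    2    0    0
 0.0000000000000000E+00    0    0    0    0
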