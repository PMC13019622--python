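&FCI NORB=6,NELEC=4,MS2=0,
 ORBSYM=1,1,1,1,1,1,
 ISYM=1,
&END
 1.6585512054750200E+00    1    1    1    1
-1.1194578050708891E-01    2    1    1    1
 1.3398027340117580E-02    2    1    2    1
 3.6732231187421188E-01    2    2    1    1
 6.2593077626712451E-03    2    2    2    1
 4.8766477020847393E-01    2    2    2    2
-1.3853106913547145E-01    3    1    1    1
 1.1230657084157880E-02    3    1    2    1
-1.5926848699076460E-02    3    1    2    2
 2.1655522701031080E-02    3    1    3    1
 1.3344011246912344E-02    3    2    1    1
-3.3634803774642602E-03    3    2    2    1
-4.8493253684944872E-02    3    2    2    2
 1.7928724910996002E-04    3    2    3    1
 1.3012969198320639E-02    3    2    3    2
 3.9565431480146140E-01    3    3    1    1
-1.1065300504451430E-02    3    3    2    1
 2.2375594199127419E-01    3    3    2    2
 1.8334180976663000E-03    3    3    3    1
 7.4168784632481603E-03    3    3    3    2
 3.3793604771650204E-01    3    3    3    3
 9.8179421647418101E-03    4    1    4    1
 7.4926033940862372E-03    4    2    4    1
 2.3450666420840989E-02    4    2    4    2
 1.0256861886241734E-02    4    3    4    1
 1.9272527586369496E-02    4    3    4    2
 4.1277817658866775E-02    4    3    4    3
 3.9631891996548058E-01    4    4    1    1
-4.3670884606167191E-03    4    4    2    1
 2.7042309682970456E-01    4    4    2    2
-4.9737129233133996E-03    4    4    3    1
 5.7118144499928511E-03    4    4    3    2
 2.8200402117008849E-01    4    4    3    3
 3.1294551115940927E-01    4    4    4    4
 9.8179421647418084E-03    5    1    5    1
 7.4926033940862381E-03    5    2    5    1
 2.3450666420840979E-02    5    2    5    2
 1.0256861886241735E-02    5    3    5    1
 1.9272527586369489E-02    5    3    5    2
 4.1277817658866768E-02    5    3    5    3
 1.6869139513690998E-02    5    4    5    4
 3.9631891996548058E-01    5    5    1    1
-4.3670884606167269E-03    5    5    2    1
 2.7042309682970450E-01    5    5    2    2
-4.9737129233134135E-03    5    5    3    1
 5.7118144499928511E-03    5    5    3    2
 2.8200402117008849E-01    5    5    3    3
 2.7920723213202719E-01    5    5    4    4
 3.1294551115940927E-01    5    5    5    5
 5.2629939342529027E-02    6    1    1    1
-8.8778018623944417E-03    6    1    2    1
-6.8042193333903399E-03    6    1    2    2
-2.3077177813135750E-03    6    1    3    1
 1.6694806427114506E-03    6    1    3    2
 1.0407371586358237E-02    6    1    3    3
 5.7270264751538270E-04    6    1    4    4
 5.7270264751538270E-04    6    1    5    5
 8.4905655503802451E-03    6    1    6    1
-4.0902407171529147E-02    6    2    1    1
 4.7422284446176268E-03    6    2    2    1
 1.2705744488007426E-01    6    2    2    2
 5.0041486786157744E-04    6    2    3    1
-3.4539807850226152E-02    6    2    3    2
-1.2281523058177462E-02    6    2    3    3
-1.6031779990536559E-02    6    2    4    4
-1.6031779990536559E-02    6    2    5    5
 1.2774914607439653E-04    6    2    6    1
 1.2387125059239430E-01    6    2    6    2
 1.7645575976114897E-02    6    3    1    1
-3.6935348629530979E-03    6    3    2    1
-5.1340261445230545E-02    6    3    2    2
 4.4009936155375443E-03    6    3    3    1
 9.3564291288558213E-03    6    3    3    2
 3.5981950938458830E-02    6    3    3    3
 2.1936707924602372E-03    6    3    4    4
 2.1936707924602372E-03    6    3    5    5
 4.3021329960138592E-03    6    3    6    1
-3.1856100673791583E-02    6    3    6    2
 2.6436465036630673E-02    6    3    6    3
-6.1081143917208801E-03    6    4    4    1
-1.9574798871741760E-02    6    4    4    2
-1.3732300346310162E-02    6    4    4    3
 1.9713280487892518E-02    6    4    6    4
-6.1081143917208792E-03    6    5    5    1
-1.9574798871741756E-02    6    5    5    2
-1.3732300346310159E-02    6    5    5    3
 1.9713280487892518E-02    6    5    6    5
 3.6174303549630388E-01    6    6    1    1
 3.3176984771839720E-03    6    6    2    1
 4.5404588902838239E-01    6    6    2    2
-1.1337417272484673E-02    6    6    3    1
-4.3292912210739561E-02    6    6    3    2
 2.4146846706315539E-01    6    6    3    3
 2.6819555654683208E-01    6    6    4    4
 2.6819555654683203E-01    6    6    5    5
-3.0272310609353601E-03    6    6    6    1
 1.3453519196977987E-01    6    6    6    2
-4.4051746521444106E-02    6    6    6    3
 4.5396189844671131E-01    6    6    6    6
-4.7284419798274877E+00    1    1    0    0
 1.0568647291787236E-01    2    1    0    0
-1.4946161063028436E+00    2    2    0    0
 1.6702128622196488E-01    3    1    0    0
 3.3035895020610891E-02    3    2    0    0
-1.1258901728092503E+00    3    3    0    0
-1.1362769993713222E+00    4    4    0    0
-1.1362769993713222E+00    5    5    0    0
-3.4279272225506523E-02    6    1    0    0
-5.4130431999153301E-02    6    2    0    0
 3.0541842362294073E-02    6    3    0    0
-9.5008675633094686E-01    6    6    0    0
 9.9538004436641803E-01    0    0    0    0
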