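CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1                      
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N  
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C  
ATOM      3  HA  ALA A   1       1.817  -0.524  -0.886  1.00  0.00           H  
ATOM      4  CB  ALA A   1       1.959  -0.731   1.236  1.00  0.00           C  
ATOM      5  HB1 ALA A   1       1.594  -1.758   1.224  1.00  0.00           H  
ATOM      6  HB2 ALA A   1       3.049  -0.734   1.240  1.00  0.00           H  
ATOM      7  HB3 ALA A   1       1.594  -0.227   2.130  1.00  0.00           H  
ATOM      8  C   ALA A   1       2.009   1.422   0.000  1.00  0.00           C  
ATOM      9  O   ALA A   1       2.910   1.749   0.773  1.00  0.00           O  
ATOM     10  N   ALA A   2       1.463   2.263  -0.872  1.00  0.00           N  
ATOM     11  H   ALA A   2       0.728   1.930  -1.479  1.00  0.00           H  
ATOM     12  CA  ALA A   2       1.899   3.650  -0.974  1.00  0.00           C  
ATOM     13  HA  ALA A   2       1.291   4.164  -1.719  1.00  0.00           H  
ATOM     14  CB  ALA A   2       3.352   3.687  -1.422  1.00  0.00           C  
ATOM     15  HB1 ALA A   2       3.446   3.202  -2.394  1.00  0.00           H  
ATOM     16  HB2 ALA A   2       3.683   4.723  -1.500  1.00  0.00           H  
ATOM     17  HB3 ALA A   2       3.971   3.163  -0.694  1.00  0.00           H  
ATOM     18  C   ALA A   2       1.768   4.370   0.364  1.00  0.00           C  
ATOM     19  O   ALA A   2       2.689   5.059   0.802  1.00  0.00           O  
ATOM     20  N   ALA A   3       0.618   4.205   1.008  1.00  0.00           N  
ATOM     21  H   ALA A   3      -0.098   3.626   0.593  1.00  0.00           H  
ATOM     22  CA  ALA A   3       0.364   4.838   2.297  1.00  0.00           C  
ATOM     23  HA  ALA A   3      -0.618   4.534   2.659  1.00  0.00           H  
ATOM     24  CB  ALA A   3       0.373   6.349   2.124  1.00  0.00           C  
ATOM     25  HB1 ALA A   3      -0.403   6.639   1.415  1.00  0.00           H  
ATOM     26  HB2 ALA A   3       0.184   6.827   3.085  1.00  0.00           H  
ATOM     27  HB3 ALA A   3       1.346   6.666   1.746  1.00  0.00           H  
ATOM     28  C   ALA A   3       1.421   4.443   3.323  1.00  0.00           C  
ATOM     29  O   ALA A   3       1.961   5.294   4.030  1.00  0.00           O  
TER      30      ALA A   3                                                      
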