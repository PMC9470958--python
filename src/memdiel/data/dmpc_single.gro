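synthetic single DMPC molecule (generated geometry, CHARMM36-style names)
  118
    1DMPC     N    1   0.500   0.524   2.200
    1DMPC   C13    2   0.500   0.530   2.280
    1DMPC  H13A    3   0.564   0.574   2.290
    1DMPC  H13B    4   0.468   0.590   2.258
    1DMPC  H13C    5   0.551   0.577   2.240
    1DMPC   C14    6   0.500   0.530   2.280
    1DMPC  H14A    7   0.468   0.494   2.277
    1DMPC  H14B    8   0.491   0.531   2.260
    1DMPC  H14C    9   0.579   0.577   2.284
    1DMPC   C15   10   0.500   0.530   2.280
    1DMPC  H15A   11   0.578   0.484   2.290
    1DMPC  H15B   12   0.518   0.457   2.253
    1DMPC  H15C   13   0.502   0.524   2.243
    1DMPC   C12   14   0.500   0.502   2.100
    1DMPC  H12A   15   0.521   0.504   2.133
    1DMPC  H12B   16   0.460   0.423   2.100
    1DMPC   C11   17   0.500   0.477   2.000
    1DMPC  H11A   18   0.531   0.430   1.975
    1DMPC  H11B   19   0.421   0.530   1.990
    1DMPC     P   20   0.500   0.470   1.900
    1DMPC   O13   21   0.500   0.474   1.980
    1DMPC   O14   22   0.500   0.471   1.950
    1DMPC   O11   23   0.500   0.479   1.830
    1DMPC   O12   24   0.500   0.474   1.860
    1DMPC    C1   25   0.500   0.501   1.740
    1DMPC    HA   26   0.463   0.562   1.712
    1DMPC    HB   27   0.556   0.524   1.741
    1DMPC    C2   28   0.350   0.524   1.640
    1DMPC    HS   29   0.285   0.531   1.659
    1DMPC    C3   30   0.650   0.521   1.660
    1DMPC    HX   31   0.709   0.499   1.661
    1DMPC    HY   32   0.579   0.503   1.668
    1DMPC   O21   33   0.350   0.530   1.560
    1DMPC   C21   34   0.350   0.524   1.500
    1DMPC   O22   35   0.350   0.527   1.520
    1DMPC   C22   36   0.350   0.506   1.420
    1DMPC   H2R   37   0.294   0.557   1.406
    1DMPC   H2S   38   0.427   0.521   1.410
    1DMPC   C23   39   0.350   0.479   1.310
    1DMPC   H3R   40   0.372   0.507   1.318
    1DMPC   H3S   41   0.340   0.437   1.282
    1DMPC   C24   42   0.350   0.471   1.200
    1DMPC   H4R   43   0.285   0.545   1.192
    1DMPC   H4S   44   0.377   0.439   1.177
    1DMPC   C25   45   0.350   0.489   1.090
    1DMPC   H5R   46   0.376   0.430   1.120
    1DMPC   H5S   47   0.421   0.553   1.118
    1DMPC   C26   48   0.350   0.517   0.980
    1DMPC   H6R   49   0.293   0.468   0.986
    1DMPC   H6S   50   0.358   0.466   1.014
    1DMPC   C27   51   0.350   0.530   0.870
    1DMPC   H7R   52   0.373   0.541   0.901
    1DMPC   H7S   53   0.336   0.488   0.860
    1DMPC   C28   54   0.350   0.516   0.760
    1DMPC   H8R   55   0.410   0.511   0.723
    1DMPC   H8S   56   0.322   0.556   0.764
    1DMPC   C29   57   0.350   0.487   0.650
    1DMPC   H9R   58   0.330   0.412   0.612
    1DMPC   H9S   59   0.425   0.513   0.620
    1DMPC  C210   60   0.350   0.470   0.540
    1DMPC  H10R   61   0.354   0.530   0.534
    1DMPC  H10S   62   0.364   0.500   0.528
    1DMPC  C211   63   0.350   0.480   0.430
    1DMPC  H11R   64   0.353   0.522   0.418
    1DMPC  H11S   65   0.294   0.549   0.463
    1DMPC  C212   66   0.350   0.508   0.320
    1DMPC  H12R   67   0.390   0.557   0.280
    1DMPC  H12S   68   0.337   0.558   0.291
    1DMPC  C213   69   0.350   0.528   0.210
    1DMPC  H13R   70   0.371   0.575   0.171
    1DMPC  H13S   71   0.386   0.485   0.211
    1DMPC  C214   72   0.350   0.523   0.100
    1DMPC  H14R   73   0.328   0.472   0.076
    1DMPC  H14S   74   0.422   0.535   0.088
    1DMPC  H14T   75   0.313   0.596   0.087
    1DMPC   O31   76   0.650   0.530   1.580
    1DMPC   C31   77   0.650   0.527   1.520
    1DMPC   O32   78   0.650   0.529   1.540
    1DMPC   C32   79   0.650   0.512   1.440
    1DMPC   H2X   80   0.727   0.514   1.436
    1DMPC   H2Y   81   0.713   0.550   1.442
    1DMPC   C33   82   0.650   0.483   1.330
    1DMPC   H3X   83   0.638   0.544   1.336
    1DMPC   H3Y   84   0.718   0.414   1.323
    1DMPC   C34   85   0.650   0.470   1.220
    1DMPC   H4X   86   0.653   0.542   1.214
    1DMPC   H4Y   87   0.699   0.498   1.200
    1DMPC   C35   88   0.650   0.484   1.110
    1DMPC   H5X   89   0.671   0.559   1.127
    1DMPC   H5Y   90   0.634   0.436   1.097
    1DMPC   C36   91   0.650   0.512   1.000
    1DMPC   H6X   92   0.604   0.579   0.964
    1DMPC   H6Y   93   0.588   0.529   1.027
    1DMPC   C37   94   0.650   0.530   0.890
    1DMPC   H7X   95   0.665   0.555   0.888
    1DMPC   H7Y   96   0.724   0.524   0.875
    1DMPC   C38   97   0.650   0.520   0.780
    1DMPC   H8X   98   0.672   0.470   0.790
    1DMPC   H8Y   99   0.636   0.562   0.745
    1DMPC   C39  100   0.650   0.492   0.670
    1DMPC   H9X  101   0.687   0.431   0.695
    1DMPC   H9Y  102   0.698   0.553   0.703
    1DMPC  C310  103   0.650   0.472   0.560
    1DMPC  H10X  104   0.717   0.399   0.562
    1DMPC  H10Y  105   0.573   0.432   0.522
    1DMPC  C311  106   0.650   0.476   0.450
    1DMPC  H11X  107   0.600   0.487   0.430
    1DMPC  H11Y  108   0.664   0.423   0.413
    1DMPC  C312  109   0.650   0.502   0.340
    1DMPC  H12X  110   0.573   0.472   0.354
    1DMPC  H12Y  111   0.656   0.552   0.375
    1DMPC  C313  112   0.650   0.526   0.230
    1DMPC  H13X  113   0.668   0.477   0.243
    1DMPC  H13Y  114   0.576   0.575   0.236
    1DMPC  C314  115   0.650   0.526   0.120
    1DMPC  H14X  116   0.707   0.455   0.157
    1DMPC  H14Y  117   0.621   0.464   0.107
    1DMPC  H14Z  118   0.698   0.497   0.130
   1.00000   1.00000   3.00000
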