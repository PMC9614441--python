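genotype,is_vinifera,gc_max,e_max,pgs50,gs_slope,psi_gs90,g_night,g_min,pi0,epsilon,psi_tlp,c_ft,c_tlp,p50_leaf,p12_leaf,p88_leaf,plc_slope,hsm_p12,hsm_p50,leaf_area
Grenache,True,200.0,2.5067850974586725,-0.55,5.0,-0.989444915467244,14.0,2.15,-0.95,9.0,-1.0621118012422357,0.8040201005025126,6.737102014294997,-1.8,-0.890909090909091,-2.709090909090909,55.0,-0.09853582455815302,0.810555084532756,0.15
Vidadillo,True,180.0,2.256106587712805,-0.62,5.5,-1.0194953776974944,12.0,2.25,-1.0,10.0,-1.1111111111111112,0.7272727272727273,6.48,-1.9,-1.0666666666666664,-2.7333333333333334,60.0,0.047171288969172,0.8805046223025055,0.15
Syrah,True,260.0,3.258820626696274,-1.0,4.5,-1.4882721282969378,20.0,3.5,-1.1,11.0,-1.2222222222222223,0.6611570247933884,5.890909090909091,-1.75,-1.0833333333333335,-2.4166666666666665,75.0,-0.4049387949636043,0.2617278717030622,0.15
Semillon,True,270.0,3.3841598815692078,-1.05,4.0,-1.5993061443340548,22.0,3.8,-1.25,12.0,-1.3953488372093024,0.6037735849056604,5.136111111111111,-2.3,-1.6749999999999998,-2.925,80.0,0.075693855665945,0.700693855665945,0.15
Yiannoudi,True,230.0,2.8828028620774737,-0.85,5.0,-1.2894449154672438,18.0,1.9,-1.05,10.5,-1.1666666666666667,0.6926406926406926,6.171428571428572,-2.0,-1.2307692307692308,-2.769230769230769,65.0,-0.058675684698012986,0.7105550845327562,0.15
V. candicans,False,210.0,2.6321243523316062,-0.75,5.0,-1.189444915467244,16.0,2.6,-1.0,9.5,-1.1176470588235294,0.7619047619047619,6.404432132963989,-1.7,-0.8666666666666666,-2.533333333333333,60.0,-0.32277824880057737,0.510555084532756,0.15
V. labrusca,False,200.0,2.5067850974586725,-0.7,5.5,-1.0994953776974945,15.0,2.2,-1.05,10.0,-1.1731843575418994,0.7239819004524887,6.103047619047619,-1.95,-1.0879310344827586,-2.8120689655172413,58.0,-0.011564343214735873,0.8505046223025055,0.15
RGM,False,240.0,3.008142116950407,-0.9,4.8,-1.357755120278379,19.0,3.2,-1.15,11.5,-1.2777777777777777,0.6324110671936759,5.634782608695653,-1.85,-1.1357142857142857,-2.5642857142857145,70.0,-0.2220408345640934,0.492244879721621,0.15
V. rupestris,False,250.0,3.1334813718233407,-0.95,4.6,-1.4276575168122216,21.0,3.4,-1.2,11.0,-1.3469387755102038,0.6557377049180328,5.291460055096419,-1.7,-1.0055555555555555,-2.3944444444444444,72.0,-0.4221019612566661,0.2723424831877783,0.15
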