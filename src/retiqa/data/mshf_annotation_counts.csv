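dataset,ic_0,ic_1,blur_0,blur_1,lc_0,lc_1,overall_0,overall_1
LOCAL_1,158,41,94,105,85,114,142,57
LOCAL_2,78,25,59,44,41,62,77,26
DR_1,31,156,34,153,6,181,40,147
DR_2,36,199,120,115,78,157,117,118
GLU,45,7,48,4,42,10,50,2
NORMAL,2,24,0,26,0,26,0,26
DRIMDB,54,140,74,120,76,118,70,124
DRIVE,0,40,0,40,0,40,0,40
DR_UWF,215,285,163,337,50,450,168,332
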