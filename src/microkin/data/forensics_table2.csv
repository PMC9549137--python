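locus,pd,pe,ho,ae
mh01zha018,0.86,0.53,0.76,3.57
mh01zha034,0.87,0.46,0.72,3.54
mh03zha016,0.88,0.44,0.71,3.81
mh04zha007,0.87,0.43,0.7,3.54
mh04zha012,0.86,0.56,0.78,3.74
mh04zha020,0.85,0.55,0.77,3.53
mh04zha027a,0.89,0.58,0.79,3.94
mh04zha031,0.84,0.56,0.78,3.58
mh04zha032a,0.91,0.46,0.72,3.84
mh05zha004a,0.83,0.46,0.72,3.32
mh06zha012a,0.89,0.32,0.63,3.73
mh06zha025,0.83,0.58,0.79,3.47
mh06zha026,0.86,0.49,0.74,3.47
mh07zha014,0.87,0.47,0.73,3.7
mh07zha026,0.87,0.55,0.77,3.82
mh07zha027,0.87,0.46,0.72,3.65
mh08zha007a,0.88,0.43,0.7,3.62
mh09zha012,0.89,0.38,0.67,3.87
mh09zha017,0.87,0.47,0.73,3.57
mh09zha021,0.88,0.56,0.78,3.79
mh10zha010,0.85,0.39,0.68,3.19
mh11zha006b,0.88,0.49,0.74,3.83
mh13zha003,0.88,0.46,0.72,3.53
mh13zha008,0.84,0.49,0.74,3.52
mh14zha003,0.89,0.38,0.67,3.75
mh14zha008,0.83,0.49,0.74,3.08
mh14zha010,0.85,0.27,0.58,3.11
mh16zha013,0.88,0.56,0.78,3.86
mh18zha010a,0.88,0.51,0.75,3.74
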