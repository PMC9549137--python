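name,chromosome,positions,rsids,extent_bp
mh01zha018,1,4573068/4573134,rs4568797/rs4323680,67
mh01zha034,1,228494357/228494382,rs3795795/rs1150911,26
mh02zha025,2,68237549/68237578/68237608,rs11689307/rs11678194/rs57008743,60
mh02zha033,2,140986567/140986573,rs6739332/rs901523,7
mh03zha016,3,32037852/32037880,rs976188/rs17028710,29
mh04zha007,4,115480309/115480344/115480387,rs6819048/rs62308082/rs74383997,79
mh04zha012,4,18798844/18798877,rs6820437/rs77394386,34
mh04zha020,4,59942563/59942599,rs11941494/rs140524865,37
mh04zha027a,4,137729311/137729331/137729375,rs11936713/rs1551708/rs1551707,65
mh04zha031,4,166705962/166705990,rs11935733/rs7694605,29
mh04zha032a,4,188290891/188290908/188290915/188290948,rs3860700/rs3860701/rs11132442/rs3860702,58
mh05zha004a,5,174968649/174968732,rs2644662/rs2662178,84
mh06zha012a,6,170554249/170554250/170554285,rs6456186/rs6456187/rs6456188,37
mh06zha025,6,67847591/67847632,rs4583967/rs2503971,42
mh06zha026,6,77669385/77669395,rs323232/rs323233,11
mh07zha014,7,5156472/5156492,rs4400288/rs117753326,21
mh07zha018,7,11777712/11777747/11777769,rs9691520/rs1534234/rs1526523,58
mh07zha026,7,103539419/103539452/103539478,rs17157141/rs73183735/rs3857817,60
mh07zha027,7,122708807/122708851,rs4731077/rs4288316,45
mh08zha007a,8,4045817/4045914,rs6996226/rs35364155,98
mh09zha012,9,28320624/28320672,rs72709379/rs1331923,49
mh09zha017,9,112618165/112618187,rs10816899/rs2769142,23
mh09zha021,9,134212403/134212428,rs726171/rs2077981,26
mh10zha010,10,15035571/15035631,rs9732205/rs9731518,61
mh10zha020,10,126297208/126297257/126297261,rs11245314/rs7079225/rs7079227,54
mh11zha006b,11,124823941/124823950/124823981,rs3809057/rs3809056/rs3809055,41
mh11zha010,11,3479453/3479464/3479478,rs10834159/rs28508343/rs12365855,26
mh12zha012,12,713677/713712/713741,rs61916660/rs2535397/rs11063832,65
mh12zha014,12,20553325/20553347,rs11045217/rs201378364,23
mh13zha003,13,59822210/59822229/59822240,rs2874768/rs12870119/rs138891898,31
mh13zha008,13,98640318/98640386,rs592246/rs588144,69
mh14zha003,14,72252135/72252139/72252142,rs4902946/rs8012670/rs4902947,8
mh14zha008,14,22095528/22095573,rs185847116/rs34904279,46
mh14zha010,14,77688982/77689033/77689054,rs10400728/rs72728998/rs9323637,73
mh16zha013,16,58900991/58901029/58901035,rs9935162/rs76244992/rs9935173,45
mh18zha010a,18,844106/844110/844130/844136/844145,rs7228601/rs7236768/rs8084713/rs190860816/rs2846762,40
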