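item_id,item_total_r,alpha_if_deleted,citc,loading,alpha,beta1,beta2,beta3,beta4,avg_info
CRF1,0.563,0.781,0.435,0.566,0.704,-2.061,-0.731,-2.360,-0.049,0.425
CRF2,0.639,0.773,0.511,0.639,0.789,-1.743,-0.280,-1.199,1.858,0.489
CRF3,0.674,0.770,0.531,0.644,0.707,-0.921,-0.177,-0.862,0.615,0.480
CRF4,0.571,0.777,0.476,0.583,0.661,-1.055,-1.790,-1.351,0.850,0.399
CRF5,0.582,0.777,0.477,0.569,0.572,-0.488,-1.669,-1.461,0.168,0.353
CRF6,0.620,0.768,0.558,0.645,0.987,-1.681,-0.915,-1.594,0.190,0.682
CRF7,0.338,0.808,0.192,0.238,0.194,-2.969,-2.959,-0.955,3.232,0.050
CRF8,0.609,0.774,0.500,0.579,0.686,-1.755,-1.207,-0.831,1.453,0.402
CRF9,0.675,0.767,0.549,0.661,0.849,-0.831,-0.921,-0.414,1.227,0.581
CRF10,0.585,0.779,0.456,0.523,0.522,-1.094,-1.381,-0.912,0.268,0.304
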