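pair_id,mirna_id,primary,metastasis
P1,miRNA20a,LOW,LOW
P1,miRNA21,LOW,LOW
P1,miRNA29a,HIGH,HIGH
P1,miRNA31,LOW,HIGH
P1,miRNA92,LOW,LOW
P1,miRNA224,LOW,LOW
P2,miRNA20a,HIGH,HIGH
P2,miRNA21,LOW,LOW
P2,miRNA29a,HIGH,HIGH
P2,miRNA31,HIGH,HIGH
P2,miRNA92,HIGH,LOW
P2,miRNA224,HIGH,LOW
P3,miRNA20a,HIGH,HIGH
P3,miRNA21,LOW,LOW
P3,miRNA29a,LOW,LOW
P3,miRNA31,LOW,NORMAL
P3,miRNA92,HIGH,LOW
P3,miRNA224,LOW,LOW
P4,miRNA20a,HIGH,HIGH
P4,miRNA21,LOW,LOW
P4,miRNA29a,LOW,NORMAL
P4,miRNA31,LOW,LOW
P4,miRNA92,LOW,HIGH
P4,miRNA224,LOW,LOW
P5,miRNA20a,LOW,HIGH
P5,miRNA21,LOW,LOW
P5,miRNA29a,LOW,LOW
P5,miRNA31,LOW,LOW
P5,miRNA92,LOW,LOW
P5,miRNA224,LOW,HIGH
P6,miRNA20a,LOW,LOW
P6,miRNA21,LOW,LOW
P6,miRNA29a,LOW,LOW
P6,miRNA31,LOW,LOW
P6,miRNA92,LOW,LOW
P6,miRNA224,LOW,LOW
P7,miRNA20a,LOW,HIGH
P7,miRNA21,LOW,LOW
P7,miRNA29a,LOW,LOW
P7,miRNA31,LOW,LOW
P7,miRNA92,LOW,LOW
P7,miRNA224,LOW,HIGH
P8,miRNA20a,LOW,HIGH
P8,miRNA21,LOW,LOW
P8,miRNA29a,HIGH,HIGH
P8,miRNA31,LOW,LOW
P8,miRNA92,LOW,LOW
P8,miRNA224,LOW,HIGH
P9,miRNA20a,LOW,LOW
P9,miRNA21,LOW,LOW
P9,miRNA29a,HIGH,HIGH
P9,miRNA31,LOW,LOW
P9,miRNA92,HIGH,LOW
P9,miRNA224,LOW,LOW
P10,miRNA20a,LOW,LOW
P10,miRNA21,LOW,LOW
P10,miRNA29a,LOW,LOW
P10,miRNA31,LOW,LOW
P10,miRNA92,LOW,LOW
P10,miRNA224,LOW,LOW
P11,miRNA20a,LOW,LOW
P11,miRNA21,LOW,LOW
P11,miRNA29a,HIGH,HIGH
P11,miRNA31,HIGH,LOW
P11,miRNA92,HIGH,LOW
P11,miRNA224,LOW,LOW
P12,miRNA20a,HIGH,LOW
P12,miRNA21,LOW,LOW
P12,miRNA29a,HIGH,LOW
P12,miRNA31,HIGH,HIGH
P12,miRNA92,HIGH,LOW
P12,miRNA224,HIGH,HIGH
P13,miRNA20a,HIGH,LOW
P13,miRNA21,LOW,LOW
P13,miRNA29a,HIGH,HIGH
P13,miRNA31,LOW,LOW
P13,miRNA92,HIGH,LOW
P13,miRNA224,LOW,LOW
P14,miRNA20a,HIGH,HIGH
P14,miRNA21,LOW,LOW
P14,miRNA29a,LOW,LOW
P14,miRNA31,LOW,LOW
P14,miRNA92,HIGH,HIGH
P14,miRNA224,LOW,LOW
P15,miRNA20a,HIGH,LOW
P15,miRNA21,LOW,LOW
P15,miRNA29a,LOW,LOW
P15,miRNA31,LOW,LOW
P15,miRNA92,LOW,LOW
P15,miRNA224,LOW,LOW
P16,miRNA20a,LOW,LOW
P16,miRNA21,LOW,LOW
P16,miRNA29a,LOW,LOW
P16,miRNA31,LOW,LOW
P16,miRNA92,LOW,LOW
P16,miRNA224,LOW,LOW
P17,miRNA20a,HIGH,LOW
P17,miRNA21,LOW,HIGH
P17,miRNA29a,LOW,HIGH
P17,miRNA31,LOW,LOW
P17,miRNA92,HIGH,HIGH
P17,miRNA224,LOW,LOW
P18,miRNA20a,HIGH,HIGH
P18,miRNA21,LOW,LOW
P18,miRNA29a,HIGH,LOW
P18,miRNA31,LOW,LOW
P18,miRNA92,HIGH,LOW
P18,miRNA224,LOW,LOW
P19,miRNA20a,HIGH,HIGH
P19,miRNA21,LOW,LOW
P19,miRNA29a,HIGH,LOW
P19,miRNA31,LOW,LOW
P19,miRNA92,HIGH,LOW
P19,miRNA224,LOW,LOW
P20,miRNA20a,HIGH,LOW
P20,miRNA21,LOW,LOW
P20,miRNA29a,HIGH,LOW
P20,miRNA31,LOW,LOW
P20,miRNA92,HIGH,LOW
P20,miRNA224,LOW,LOW
P22,miRNA20a,NORMAL,LOW
P22,miRNA21,LOW,LOW
P22,miRNA29a,HIGH,LOW
P22,miRNA31,LOW,HIGH
P22,miRNA92,HIGH,LOW
P22,miRNA224,LOW,LOW
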