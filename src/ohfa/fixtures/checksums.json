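{
 "table1.csv": "810cf1d168fa4407479d424cf93aa9268f9ec7ceb1af8922d79f31d1cf28d430",
 "table2.csv": "2420e4c447dcea9afafbb4279e823ed7b459c259b5a342fe0f6a45d1436bf158",
 "table3.csv": "7a3b023767f20a0bdf3d7f8f053ce7941fb7923be7b832db5335841ceaf2abf5",
 "table4.csv": "28106859d54680436f33376b3ceabc50022b690cfb6fc3e735ab41c7fcd42014",
 "table5.csv": "1c086bff8844e1d1912bb721848486a111fcb9d54a871106ce8fea06a83daec1",
 "table6.csv": "c45fdabf090cb403bd5869474ac917718ed2484b762b75f54bac27f40b270431"
}
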