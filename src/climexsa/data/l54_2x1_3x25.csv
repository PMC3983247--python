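C1_2lv,C2,C3,C4,C5,C6,C7,C8,C9,C10,C11,C12,C13,C14,C15,C16,C17,C18,C19,C20,C21,C22,C23,C24,C25,C26
1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
1,2,3,2,3,2,3,2,3,1,1,1,2,2,3,1,1,1,1,2,2,2,2,2,2,3
1,3,2,3,2,3,2,3,2,1,1,1,3,3,2,1,1,1,1,3,3,3,3,3,3,2
1,2,2,2,2,2,2,2,2,1,2,2,1,2,2,2,2,2,2,1,1,1,1,1,2,2
1,3,1,3,1,3,1,3,1,1,2,2,2,3,1,2,2,2,2,2,2,2,2,2,3,1
1,1,3,1,3,1,3,1,3,1,2,2,3,1,3,2,2,2,2,3,3,3,3,3,1,3
1,3,3,3,3,3,3,3,3,1,3,3,1,3,3,3,3,3,3,1,1,1,1,1,3,3
1,1,2,1,2,1,2,1,2,1,3,3,2,1,2,3,3,3,3,2,2,2,2,2,1,2
1,2,1,2,1,2,1,2,1,1,3,3,3,2,1,3,3,3,3,3,3,3,3,3,2,1
1,1,1,2,2,3,3,2,2,2,1,3,3,1,1,1,3,2,2,1,2,1,3,2,3,3
1,2,3,3,1,1,2,3,1,2,1,3,1,2,3,1,3,2,2,2,3,2,1,3,1,2
1,3,2,1,3,2,1,1,3,2,1,3,2,3,2,1,3,2,2,3,1,3,2,1,2,1
1,2,2,3,3,1,1,3,3,2,2,1,3,2,2,2,1,3,3,1,2,1,3,2,1,1
1,3,1,1,2,2,3,1,2,2,2,1,1,3,1,2,1,3,3,2,3,2,1,3,2,3
1,1,3,2,1,3,2,2,1,2,2,1,2,1,3,2,1,3,3,3,1,3,2,1,3,2
1,3,3,1,1,2,2,1,1,2,3,2,3,3,3,3,2,1,1,1,2,1,3,2,2,2
1,1,2,2,3,3,1,2,3,2,3,2,1,1,2,3,2,1,1,2,3,2,1,3,3,1
1,2,1,3,2,1,3,3,2,2,3,2,2,2,1,3,2,1,1,3,1,3,2,1,1,3
1,1,1,1,1,3,3,3,3,3,2,2,3,2,2,1,3,3,1,1,3,2,2,1,2,2
1,2,3,2,3,1,2,1,2,3,2,2,1,3,1,1,3,3,1,2,1,3,3,2,3,1
1,3,2,3,2,2,1,2,1,3,2,2,2,1,3,1,3,3,1,3,2,1,1,3,1,3
1,2,2,2,2,1,1,1,1,3,3,3,3,3,3,2,1,1,2,1,3,2,2,1,3,3
1,3,1,3,1,2,3,2,3,3,3,3,1,1,2,2,1,1,2,2,1,3,3,2,1,2
1,1,3,1,3,3,2,3,2,3,3,3,2,2,1,2,1,1,2,3,2,1,1,3,2,1
1,3,3,3,3,2,2,2,2,3,1,1,3,1,1,3,2,2,3,1,3,2,2,1,1,1
1,1,2,1,2,3,1,3,1,3,1,1,1,2,3,3,2,2,3,2,1,3,3,2,2,3
1,2,1,2,1,1,3,1,3,3,1,1,2,3,2,3,2,2,3,3,2,1,1,3,3,2
2,1,1,3,3,1,1,2,2,1,3,2,1,3,3,1,1,2,3,1,2,3,2,3,2,2
2,2,3,1,2,2,3,3,1,1,3,2,2,1,2,1,1,2,3,2,3,1,3,1,3,1
2,3,2,2,1,3,2,1,3,1,3,2,3,2,1,1,1,2,3,3,1,2,1,2,1,3
2,2,2,1,1,2,2,3,3,1,1,3,1,1,1,2,2,3,1,1,2,3,2,3,3,3
2,3,1,2,3,3,1,1,2,1,1,3,2,2,3,2,2,3,1,2,3,1,3,1,1,2
2,1,3,3,2,1,3,2,1,1,1,3,3,3,2,2,2,3,1,3,1,2,1,2,2,1
2,3,3,2,2,3,3,1,1,1,2,1,1,2,2,3,3,1,2,1,2,3,2,3,1,1
2,1,2,3,1,1,2,2,3,1,2,1,2,3,1,3,3,1,2,2,3,1,3,1,2,3
2,2,1,1,3,2,1,3,2,1,2,1,3,1,3,3,3,1,2,3,1,2,1,2,3,2
2,1,1,2,2,2,2,3,3,2,3,1,2,3,3,1,2,3,2,1,3,3,1,2,1,1
2,2,3,3,1,3,1,1,2,2,3,1,3,1,2,1,2,3,2,2,1,1,2,3,2,3
2,3,2,1,3,1,3,2,1,2,3,1,1,2,1,1,2,3,2,3,2,2,3,1,3,2
2,2,2,3,3,3,3,1,1,2,1,2,2,1,1,2,3,1,3,1,3,3,1,2,2,2
2,3,1,1,2,1,2,2,3,2,1,2,3,2,3,2,3,1,3,2,1,1,2,3,3,1
2,1,3,2,1,2,1,3,2,2,1,2,1,3,2,2,3,1,3,3,2,2,3,1,1,3
2,3,3,1,1,1,1,2,2,2,2,3,2,2,2,3,1,2,1,1,3,3,1,2,3,3
2,1,2,2,3,2,3,3,1,2,2,3,3,3,1,3,1,2,1,2,1,1,2,3,1,2
2,2,1,3,2,3,2,1,3,2,2,3,1,1,3,3,1,2,1,3,2,2,3,1,2,1
2,1,1,3,3,2,2,1,1,3,2,3,2,2,2,1,2,1,3,1,1,2,3,3,3,3
2,2,3,1,2,3,1,2,3,3,2,3,3,3,1,1,2,1,3,2,2,3,1,1,1,2
2,3,2,2,1,1,3,3,2,3,2,3,1,1,3,1,2,1,3,3,3,1,2,2,2,1
2,2,2,1,1,3,3,2,2,3,3,1,2,3,3,2,3,2,1,1,1,2,3,3,1,1
2,3,1,2,3,1,2,3,1,3,3,1,3,1,2,2,3,2,1,2,2,3,1,1,2,3
2,1,3,3,2,2,1,1,3,3,3,1,1,2,1,2,3,2,1,3,3,1,2,2,3,2
2,3,3,2,2,1,1,3,3,3,1,2,2,1,1,3,1,3,2,1,1,2,3,3,2,2
2,1,2,3,1,2,3,1,2,3,1,2,3,2,3,3,1,3,2,2,2,3,1,1,3,1
2,2,1,1,3,3,2,2,1,3,1,2,1,3,2,3,1,3,2,3,3,1,2,2,1,3
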