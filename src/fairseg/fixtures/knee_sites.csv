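race,gender,site,count
Black,Male,A,43
Black,Male,B,2
Black,Male,C,4
Black,Male,D,14
Black,Male,E,23
White,Male,A,23
White,Male,B,36
White,Male,C,56
White,Male,D,64
White,Male,E,15
Black,Female,A,80
Black,Female,B,4
Black,Female,C,21
Black,Female,D,31
Black,Female,E,38
White,Female,A,29
White,Female,B,67
White,Female,C,73
White,Female,D,60
White,Female,E,24
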