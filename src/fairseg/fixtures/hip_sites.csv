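race,gender,site,count
Black,Male,A,45
Black,Male,B,3
Black,Male,C,8
Black,Male,D,11
Black,Male,E,27
White,Male,A,28
White,Male,B,46
White,Male,C,91
White,Male,D,37
White,Male,E,28
Black,Female,A,112
Black,Female,B,2
Black,Female,C,10
Black,Female,D,25
Black,Female,E,75
White,Female,A,28
White,Female,B,78
White,Female,C,40
White,Female,D,45
White,Female,E,22
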