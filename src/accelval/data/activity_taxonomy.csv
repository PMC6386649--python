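activity,location,intensity,locomotion,duration_min,n_participants
Computer work,upper,sedentary,no,8,11
Ironing,upper,light,no,8,12
Yoga,total,light,no,8,8
Shopping,total,light,no,8,13
Laundry,upper,light,no,8,9
Washing windows,upper,moderate,no,8,15
Home maintenance,upper,moderate,no,8,14
Replacing bed sheet,upper,moderate,no,8,13
Mopping,upper,moderate,no,8,13
Trash removal,total,moderate,no,8,13
Heavy lifting,total,moderate,no,8,12
Leisure walk,lower,moderate,yes,8,9
Rapid walk,lower,moderate,yes,8,9
Walk at RPE 1,lower,moderate,yes,5,14
Walk at RPE 5,lower,moderate,yes,5,13
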