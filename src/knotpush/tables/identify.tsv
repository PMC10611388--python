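name	crossing_number	jones	handedness	determinant
3_1	3	4:1,12:1,16:-1	right	3
4_1	4	-8:1,-4:-1,0:1,4:-1,8:1	amphichiral	5
5_1	5	8:1,16:1,20:-1,24:1,28:-1	right	5
5_2	5	4:1,8:-1,12:2,16:-1,20:1,24:-1	right	7
6_1	6	-8:1,-4:-1,0:2,4:-2,8:1,12:-1,16:1	right	9
6_2	6	-4:1,0:-1,4:2,8:-2,12:2,16:-2,20:1	right	11
6_3	6	-12:-1,-8:2,-4:-2,0:3,4:-2,8:2,12:-1	amphichiral	13
7_1	7	12:1,20:1,24:-1,28:1,32:-1,36:1,40:-1	right	7
7_2	7	4:1,8:-1,12:2,16:-2,20:2,24:-1,28:1,32:-1	right	11
7_3	7	8:1,12:-1,16:2,20:-2,24:3,28:-2,32:1,36:-1	right	13
7_4	7	4:1,8:-2,12:3,16:-2,20:3,24:-2,28:1,32:-1	right	15
7_5	7	8:1,12:-1,16:3,20:-3,24:3,28:-3,32:2,36:-1	right	17
7_6	7	-4:1,0:-2,4:3,8:-3,12:4,16:-3,20:2,24:-1	right	19
7_7	7	-12:-1,-8:3,-4:-3,0:4,4:-4,8:3,12:-2,16:1	right	21
8_1	8	-8:1,-4:-1,0:2,4:-2,8:2,12:-2,16:1,20:-1,24:1	right	13
8_19	8	12:1,20:1,32:-1	right	3
9_1	9	16:1,24:1,28:-1,32:1,36:-1,40:1,44:-1,48:1,52:-1	right	9
9_2	9	4:1,8:-1,12:2,16:-2,20:2,24:-2,28:2,32:-1,36:1,40:-1	right	15
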