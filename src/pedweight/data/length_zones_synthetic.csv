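lower_cm,upper_cm,label,weight_kg
45.9,50.3,Z01,3.6
50.3,54.6,Z02,4.3
54.6,59.0,Z03,5.1
59.0,63.4,Z04,6.0
63.4,67.8,Z05,6.9
67.8,72.1,Z06,7.9
72.1,76.5,Z07,9.0
76.5,80.9,Z08,10.2
80.9,85.3,Z09,11.4
85.3,89.6,Z10,12.7
89.6,94.0,Z11,14.1
94.0,98.4,Z12,15.5
98.4,102.8,Z13,17.0
102.8,107.1,Z14,18.6
107.1,111.5,Z15,20.3
111.5,115.9,Z16,22.0
115.9,120.3,Z17,23.9
120.3,124.6,Z18,25.8
124.6,129.0,Z19,27.7
129.0,133.4,Z20,29.8
133.4,137.8,Z21,31.9
137.8,142.1,Z22,34.1
142.1,146.5,Z23,36.4
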