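AA	PHI_BIN	PSI_BIN	PROB	CHI1	CHI2	CHI3	CHI4
A	-60	-50	1.000				
A	-120	130	1.000				
C	-60	-50	0.520	-65.0			
C	-60	-50	0.260	-177.0			
C	-60	-50	0.220	62.0			
C	-120	130	0.450	-65.0			
C	-120	130	0.330	-177.0			
C	-120	130	0.220	62.0			
D	-60	-50	0.520	-70.0	-15.0		
D	-60	-50	0.320	-177.0	5.0		
D	-60	-50	0.160	62.0	-10.0		
D	-120	130	0.460	-70.0	-15.0		
D	-120	130	0.360	-177.0	5.0		
D	-120	130	0.180	62.0	-10.0		
E	-60	-50	0.360	-67.0	180.0	-10.0	
E	-60	-50	0.260	-177.0	177.0	0.0	
E	-60	-50	0.240	-65.0	-65.0	-40.0	
E	-60	-50	0.140	-177.0	65.0	10.0	
E	-120	130	0.330	-67.0	180.0	-10.0	
E	-120	130	0.270	-177.0	177.0	0.0	
E	-120	130	0.250	-65.0	-65.0	-40.0	
E	-120	130	0.150	-177.0	65.0	10.0	
F	-60	-50	0.460	-65.0	95.0		
F	-60	-50	0.310	-177.0	80.0		
F	-60	-50	0.140	62.0	90.0		
F	-60	-50	0.090	-65.0	-85.0		
F	-120	130	0.420	-65.0	95.0		
F	-120	130	0.340	-177.0	80.0		
F	-120	130	0.150	62.0	90.0		
F	-120	130	0.090	-65.0	-85.0		
G	-60	-50	1.000				
G	-120	130	1.000				
H	-60	-50	0.420	-65.0	-70.0		
H	-60	-50	0.300	-177.0	80.0		
H	-60	-50	0.160	62.0	-75.0		
H	-60	-50	0.120	-65.0	165.0		
H	-120	130	0.380	-65.0	-70.0		
H	-120	130	0.320	-177.0	80.0		
H	-120	130	0.180	62.0	-75.0		
H	-120	130	0.120	-65.0	165.0		
I	-60	-50	0.620	-65.0	170.0		
I	-60	-50	0.150	62.0	170.0		
I	-60	-50	0.140	-177.0	170.0		
I	-60	-50	0.090	-65.0	-60.0		
I	-120	130	0.660	-65.0	170.0		
I	-120	130	0.140	62.0	170.0		
I	-120	130	0.130	-177.0	170.0		
I	-120	130	0.070	-65.0	-60.0		
K	-60	-50	0.360	-65.0	180.0	180.0	180.0
K	-60	-50	0.300	-177.0	180.0	180.0	180.0
K	-60	-50	0.200	-65.0	-68.0	180.0	180.0
K	-60	-50	0.140	-65.0	180.0	-68.0	180.0
K	-120	130	0.330	-65.0	180.0	180.0	180.0
K	-120	130	0.310	-177.0	180.0	180.0	180.0
K	-120	130	0.210	-65.0	-68.0	180.0	180.0
K	-120	130	0.150	-65.0	180.0	-68.0	180.0
L	-60	-50	0.560	-65.0	175.0		
L	-60	-50	0.300	-177.0	65.0		
L	-60	-50	0.080	-85.0	65.0		
L	-60	-50	0.060	-172.0	145.0		
L	-120	130	0.500	-65.0	175.0		
L	-120	130	0.340	-177.0	65.0		
L	-120	130	0.090	-85.0	65.0		
L	-120	130	0.070	-172.0	145.0		
M	-60	-50	0.300	-65.0	175.0	180.0	
M	-60	-50	0.240	-65.0	175.0	-70.0	
M	-60	-50	0.200	-65.0	-65.0	-70.0	
M	-60	-50	0.150	-177.0	175.0	180.0	
M	-60	-50	0.110	-177.0	65.0	75.0	
M	-120	130	0.270	-65.0	175.0	180.0	
M	-120	130	0.250	-65.0	175.0	-70.0	
M	-120	130	0.210	-65.0	-65.0	-70.0	
M	-120	130	0.160	-177.0	175.0	180.0	
M	-120	130	0.110	-177.0	65.0	75.0	
N	-60	-50	0.440	-65.0	-20.0		
N	-60	-50	0.270	-174.0	30.0		
N	-60	-50	0.170	62.0	-15.0		
N	-60	-50	0.120	-65.0	120.0		
N	-120	130	0.400	-65.0	-20.0		
N	-120	130	0.290	-174.0	30.0		
N	-120	130	0.190	62.0	-15.0		
N	-120	130	0.120	-65.0	120.0		
P	-60	-50	1.000				
P	-120	130	1.000				
Q	-60	-50	0.360	-67.0	180.0	-10.0	
Q	-60	-50	0.260	-177.0	177.0	0.0	
Q	-60	-50	0.240	-65.0	-65.0	-40.0	
Q	-60	-50	0.140	-177.0	65.0	10.0	
Q	-120	130	0.330	-67.0	180.0	-10.0	
Q	-120	130	0.270	-177.0	177.0	0.0	
Q	-120	130	0.250	-65.0	-65.0	-40.0	
Q	-120	130	0.150	-177.0	65.0	10.0	
R	-60	-50	0.310	-65.0	180.0	180.0	180.0
R	-60	-50	0.280	-177.0	180.0	180.0	180.0
R	-60	-50	0.220	-65.0	180.0	180.0	-85.0
R	-60	-50	0.190	-65.0	-68.0	180.0	180.0
R	-120	130	0.290	-65.0	180.0	180.0	180.0
R	-120	130	0.290	-177.0	180.0	180.0	180.0
R	-120	130	0.220	-65.0	180.0	180.0	-85.0
R	-120	130	0.200	-65.0	-68.0	180.0	180.0
S	-60	-50	0.470	-65.0			
S	-60	-50	0.310	62.0			
S	-60	-50	0.220	-176.0			
S	-120	130	0.360	62.0			
S	-120	130	0.330	-65.0			
S	-120	130	0.310	-176.0			
T	-60	-50	0.480	-60.0			
T	-60	-50	0.400	62.0			
T	-60	-50	0.120	-175.0			
T	-120	130	0.450	62.0			
T	-120	130	0.400	-60.0			
T	-120	130	0.150	-175.0			
V	-60	-50	0.620	175.0			
V	-60	-50	0.260	-60.0			
V	-60	-50	0.120	64.0			
V	-120	130	0.720	175.0			
V	-120	130	0.180	-60.0			
V	-120	130	0.100	64.0			
W	-60	-50	0.400	-65.0	95.0		
W	-60	-50	0.280	-177.0	-105.0		
W	-60	-50	0.180	-70.0	-90.0		
W	-60	-50	0.140	62.0	90.0		
W	-120	130	0.360	-65.0	95.0		
W	-120	130	0.300	-177.0	-105.0		
W	-120	130	0.200	-70.0	-90.0		
W	-120	130	0.140	62.0	90.0		
Y	-60	-50	0.460	-65.0	95.0		
Y	-60	-50	0.310	-177.0	80.0		
Y	-60	-50	0.140	62.0	90.0		
Y	-60	-50	0.090	-65.0	-85.0		
Y	-120	130	0.420	-65.0	95.0		
Y	-120	130	0.340	-177.0	80.0		
Y	-120	130	0.150	62.0	90.0		
Y	-120	130	0.090	-65.0	-85.0		
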