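	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.973	-1.812	-0.311	-0.361	-1.725	-0.752	-0.841	-1.661	-0.184	-1.589	-1.508	-0.344	-0.541	-0.406	-0.301	-0.588	-0.669	-1.479	-1.662	-1.322
C	-1.812	-3.477	-0.544	-0.554	-3.132	-1.306	-1.490	-2.975	-0.408	-2.898	-2.773	-0.692	-0.968	-0.724	-0.513	-1.071	-1.155	-2.655	-3.038	-2.494
D	-0.311	-0.544	0.680	0.697	-0.530	-0.242	-0.621	-0.472	-0.863	-0.444	-0.425	-0.110	-0.193	-0.118	-0.914	-0.181	-0.208	-0.454	-0.473	-0.366
E	-0.361	-0.554	0.697	0.712	-0.526	-0.249	-0.694	-0.495	-0.902	-0.554	-0.541	-0.112	-0.210	-0.168	-0.928	-0.167	-0.234	-0.440	-0.525	-0.407
F	-1.725	-3.132	-0.530	-0.526	-3.005	-1.253	-1.380	-2.841	-0.379	-2.766	-2.671	-0.646	-0.976	-0.688	-0.475	-0.996	-1.097	-2.525	-2.908	-2.359
G	-0.752	-1.306	-0.242	-0.249	-1.253	-0.502	-0.575	-1.177	-0.196	-1.196	-1.125	-0.268	-0.391	-0.314	-0.198	-0.451	-0.463	-1.037	-1.250	-0.954
H	-0.841	-1.490	-0.621	-0.694	-1.380	-0.575	-0.444	-1.335	0.213	-1.285	-1.232	-0.318	-0.458	-0.365	0.148	-0.442	-0.523	-1.218	-1.362	-1.152
I	-1.661	-2.975	-0.472	-0.495	-2.841	-1.177	-1.335	-2.643	-0.372	-2.621	-2.539	-0.582	-0.851	-0.648	-0.433	-0.963	-1.062	-2.402	-2.760	-2.263
K	-0.184	-0.408	-0.863	-0.902	-0.379	-0.196	0.213	-0.372	0.733	-0.371	-0.373	-0.115	-0.122	-0.063	0.712	-0.161	-0.136	-0.293	-0.369	-0.334
L	-1.589	-2.898	-0.444	-0.554	-2.766	-1.196	-1.285	-2.621	-0.371	-2.546	-2.508	-0.545	-0.879	-0.642	-0.474	-0.920	-1.017	-2.323	-2.647	-2.172
M	-1.508	-2.773	-0.425	-0.541	-2.671	-1.125	-1.232	-2.539	-0.373	-2.508	-2.374	-0.584	-0.869	-0.654	-0.427	-0.871	-0.982	-2.280	-2.605	-2.129
N	-0.344	-0.692	-0.110	-0.112	-0.646	-0.268	-0.318	-0.582	-0.115	-0.545	-0.584	-0.144	-0.183	-0.106	-0.113	-0.194	-0.265	-0.568	-0.610	-0.533
P	-0.541	-0.968	-0.193	-0.210	-0.976	-0.391	-0.458	-0.851	-0.122	-0.879	-0.869	-0.183	-0.257	-0.185	-0.160	-0.283	-0.359	-0.768	-0.919	-0.719
Q	-0.406	-0.724	-0.118	-0.168	-0.688	-0.314	-0.365	-0.648	-0.063	-0.642	-0.654	-0.106	-0.185	-0.186	-0.077	-0.236	-0.282	-0.569	-0.653	-0.506
R	-0.301	-0.513	-0.914	-0.928	-0.475	-0.198	0.148	-0.433	0.712	-0.474	-0.427	-0.113	-0.160	-0.077	0.691	-0.183	-0.185	-0.374	-0.427	-0.410
S	-0.588	-1.071	-0.181	-0.167	-0.996	-0.451	-0.442	-0.963	-0.161	-0.920	-0.871	-0.194	-0.283	-0.236	-0.183	-0.305	-0.395	-0.824	-0.989	-0.767
T	-0.669	-1.155	-0.208	-0.234	-1.097	-0.463	-0.523	-1.062	-0.136	-1.017	-0.982	-0.265	-0.359	-0.282	-0.185	-0.395	-0.395	-0.934	-1.042	-0.846
V	-1.479	-2.655	-0.454	-0.440	-2.525	-1.037	-1.218	-2.402	-0.293	-2.323	-2.280	-0.568	-0.768	-0.569	-0.374	-0.824	-0.934	-2.075	-2.422	-1.942
W	-1.662	-3.038	-0.473	-0.525	-2.908	-1.250	-1.362	-2.760	-0.369	-2.647	-2.605	-0.610	-0.919	-0.653	-0.427	-0.989	-1.042	-2.422	-2.817	-2.254
Y	-1.322	-2.494	-0.366	-0.407	-2.359	-0.954	-1.152	-2.263	-0.334	-2.172	-2.129	-0.533	-0.719	-0.506	-0.410	-0.767	-0.846	-1.942	-2.254	-1.869
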