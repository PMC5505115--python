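[211.812][154.295][261.952]Y[200.869]NMIYGAG
[168.09]PDATIVY[128.106]
DDYVI[262.263][128.148]
GVIIHE[291.835][227.31]GFY
GTCICDGGSCNC[128.125]R
[127.832]VRNGCNT[252.829]DVGIR
RDAP[215.036][170.707][196.097]IG[153.721]F
GNMFSCWSTVGMR
INIIY[128.088]
[128.115]PCGNNV[274.883]DP[227.119]
GAAGVTIINPAAGR
NAVSSD[244.341]
GVIIHEIGHVIGF
[153.983]IDI[128.103][241.226]NTIY
GDSRIWPDGVVIY
F[242.232]D[275.039][128.008]RCVY
[127.931]D[128.061][241.133]DR[184.194][174.03]PY
IEAGDV[128.029]GIGCGG
[349.495]IGITGF
[184.051]N[257.098][216.857]I[259.978]E[291.043]SIPSN
F[127.959]NHDS[204.387]D[242.74]
RDAP[215.036][170.707][196.097]IG[153.721]F
GIGIT[128.015]PCTCS[198.07]C[225.217]
INIIY[128.088]
[198.061]YITAST[234.471]D[127.861][128.324]DFA[128.058]
HYEIF[128.043]GFR
[241.121]ICAIVI[202.255]G[245.305]II[326.299]
[185.016]CC[215.047]DVANAEAW
VATYDDN[283.158]V[248.057][128.175][128.114]
I[128.164][185.033][320.151][199.846]V[128.057]V[257.079]
[258.156]GS[215.905]C[128.131]TN[142.105]
[323.223]SIDIIAS[128.107]
WVI[211.923][323.19][193.88]G[184.835]DWG[288.885]AGVVGGIV[168.053]
IA[277.273]D[217.017]F[286.991]V[275.199]
[127.947]IAEWFDVDVC
I[172.141]NFMN[128.005]R
AGADGM[212.996]DFP[127.998]
[128.05][346.235]FGWEIC[128.103]
I[128.005]NYWNNGDNG[230.782]
[234.124]IIISI[211.97]T[220.159]Y[128.131]
[217.067]VDDGS[127.933][261.153]IGGDSCC[127.973]
[202.038]TYEDN[283.238]VTF[128.109]A
WENF[229.222]FI[128.141]
IATYDDN[283.149][128.13][128.098]
WSR[225.203]IWDIAHM
[128.059]SSI[185.218]DN[127.961]AY[128.189]AGVNMATDI[275.181]
[259.057]SFADYIDYMR
AIC[262.118]N[213.308][157.942]IF[269.463]M
[128.065]PI[257.302][168.016][128.103]
WVI[213.173]FE[230.5]VEDWG[289.028]AGN[198.021]IV[168.053]
CENISTDD[214.057]R
R[169.813][231.411]ANPIGR
[127.988]AE[300.164]D[128.052]IF[128.126]I[255.151]
WVIGG[184.011]A[216.684][200.309]T[200.21][184.253][200.309][216.684]GVVGGIV[168.237]
[255.268]TCEYIEI[245.969]DSNYSEIG[224.144]
GEEYVNVFPMGIR
[256.067][269.811][259.263][227.115]GHEPHC[299.732]
[128.078][128.124]AGV[128.053]D[128.036]EHIW
[278.133]A[127.914]ARDAG[128.044]V[127.924]
TARDVA
[144.086][196.168][128.016][299.803][217.693]DNGNN[142.216][128.015]
PI[128.15]TD[276.095][260.159][226.968]
[128.069][314.204][266.04]EIIE[128.136]VGY
[128.135]G[238.403]YEDNPW
[285.246]TIT[127.957][128.38][193.725]PE[244.902][128.249]F[300.312]
IISI[211.095]ID[300.088]
[128.046]T[261.162][127.9]SAG
YWTVD[128.227]Y
GIIISI[250.013]IAHY
NAIETDVT
[127.882]GI[185.036]EGC[200.002][372.207]ICA
R[227.227]TT[154.041]V
GEND[170.749]N[270.185]AY
[128.095]EVIGVTII[143.89]TCEAH[252.229][210.281]D[274.244]
FCGC[128.12]AWNPGHC[261.261][127.94]
Y[293.065]PCDCF
R[312.174][247.035][256.156]AVN
[349.464]NDGCP[314.14]CNDW
N[128.122]AGV[128.154]DREHVW
VGGSCNDD[127.823]VCC[128.169]GG[128.002]
RIANYDD[345.981][289.109]F
WFDVDVC[128.184]GG
[256.225]F[315.247]N[251.495]W[128.071][171.981]GI[214.973]
[201.075]DDD[183.982]D[342.088][248.103][282.879]W[260.214]
FI[128.05]GDYINV
[127.979]SY[168.058]VIVG[326.398]E[257.168][128.109]D[291.254]
[243.149]R[214.248]D[228.235]I[128.113][128.353][226.9]TIY
[249.996]S[320.07]C[292.123]PMI[303.312]V
[260.294]C[274.817]N[250.295]N[229.03][250.931]INNR[248.338]
[128.075]GP[260.085][128.08]FNPGNYDEEE[269.243]
HGIPCDCGRSCI
[185.577]ERR[210.449]WIMG[220.232]
ADNRG[196.202]IW
E[310.079]DRV[128.206][127.978]
RN[172.129]A[185.125]IIMAVI
[128.089]SRD[226.149]DHIW
[241.168]D[128.065][246.052]D[306.802][314.355]EF
[144.192][184.287][171.423][244.328][212.328]AFTDD[157.983][314.318]
[271.172]AI[141.933][167.905][170.252]EEI[276.104][127.878]
Y[128.246]E[128.214]IIIF
M[169.966]D[227.167]DIA[204.21][238.193]N
[252.158][172.24]AG[128.07]IIS[346.153]
I[248.195][172.042]RTNCC[317.124][316.196]
GMDIPNIRI[198.131][274.115]
IADYE[245.445]RGF
[229.079]VNDYDCA[278.03][197.89][257.788]N[341.945]F[188.387]GGI[173.846]E[203.936][227.312][212.04]
[288.103][276.948]A[228.135]PETA[217.192]E[258.063]GH[270.214]
[141.867]GCTMGVC[262.034]G[127.99]
[170.014]T[257.226][128.082]CPAWSHER
[128.076][198.175]C[128.129][257.053]AWSH[285.151]ECR
[242.133]VECICSPSYYP[154.122][128.073]
[128.047]GI[220.146][299.366]THH[128.119]Y[196.17]E[316.185]
WVI[213.183]FE[230.39][229.002]DWG[288.987][127.905]VV[128.365]V[285.053]
[174.128]TVPVYAECGR
[128.108][128.122]NVMRIYVG
AGGASE[288.32]V[288.068]E
[174.137]GIPNASGSIGR
R[217.187][200.251]FVPVG[174.181]G
GAD[225.773][283.154][216.215]
[342.104][142.018][174.19][275.359]TCHGPNWAA[342.104]
[371.939]WNYA[199.308][128.365]STII
[128.037]SSFEDF[227.173]VDCNS[261.16]
G[216.293]CSDG[342.128]DIPC[128.288]
IGISSD[320.03]PDW[128.125]
ECI[241.167][241.217][345.95]
AAGDTN[259.089][229.905][237.813][320.42]W[128.09]
RCE[224.918]GI[128.1]DISE
[226.296]PNI[128.014][185.165]T[247.019]CNN[226.997]
[258.986]VCYC[208.258]FGV[128.123]NC[128.024]
GIRSATTPGNA[128.185]Y
[199.081]YD[225.268]DDWCCG[199.016]
[213.19][128.003]Y[127.926][299.318][275.069]R[244.958][183.934][277.077][128.226]G[141.885]
CT[224.823]CGPYY
[320.096][128.127][128.065]GTPC[128.107]CPAWSHER[289.113][174.07]
TG[128.074][128.206]FI
[260.124][257.99][260.764]DAIESEDPV[208.163]
SV[127.961][200.118]GI[315.972][128.206]E[142.111]
M[247.954][271.519]E[198.253][128.081]D[200.22]
GAG[143.963]NIFA[127.947]
[127.704]T[128.06]FCV[128.02]NG[128.165]PICP[128.162][167.895]G
G[266.174]CHAFGSNCR
[128.02]CP[235.787][198.175][143.863]G[241.815]DV[127.896][218.419]G
[269.335][262.236]S[244.714]WASFP[211.817]SA[128.235]I[269.335]
[346.178][257.117]N[215.219][298.78][217.218]ND[260.144]IG[256.421][372.04]
V[207.937]SSEY[211.831]I[326.363][319.484]
[256.849][275.401][210.175]I[252.242]TA[244.108][200.309][241.062]N[170.078]IIED[372.344]
[269.086]FGIMAP[225.403]GEIR
[200.059]VHEDNI[128.065]E[128.062]H[128.193][262.127]
[199.078]CT[297.052]F[264.084][233.709]GCPSR
[269.045]D[173.858]DPDCDC[211.944]D[173.937]D[269.044]
I[204.06]CV[128.097][297.04]
[241.241][210.11]DFYEI[170.035]SA[262.036]
[128.159]GF[218.024]D[127.978]VVIA
[262.073]I[243.142]PSNPSCR
[216.109]IVISNPDINH[260.307][226.167][128.074]
TED[128.098]V[229.139]
[128.037]SSFEDF[227.173]VDCNS[261.16]
[199.18]SIDIIAS[128.129]DVMDR
[269.086]FGIMAP[225.403]GEIR
[247.11]G[128.088]I[183.991]N[210.738][262.174][285.2]
Y[127.918]GV[143.679]I[196.241]AGR
VGSIPIDI[128.058]
[128.071]SAI[250.284]IS[127.926]N
GTIPVT[323.12]P[128.197]
[128.057]CW[283.922]E[127.782][128.342]GA
[128.066]CG[169.924]S[293.695]D[211.062]C[143.962]
HVSV[128.009]
[262.165]P[230.085]D[128.062]
[268.215]HCTCDDVC[128.023]R[275.259]Y
[274.04]TPIRIN[210.228]II[228.096]
[372.255]DEIIN[171.15]IE[200.054]E[201.127]S[226.48]HG[293.174][372.288]
NW[211.918]RIR[298.994][248.176]
[253.085]IG[200.301]T[251.496][171.357]ED
YHNN[232.454]ISII
[276.09]MISMEVG[307.07][259.494]Y
[128.205]MFTIIM[235.906]GV[215.128]
[245.288]RA[260.078]NTSTIGTA[212.046]R
S[246.297][301.019]IVS[170.255]H
RT[255.953][231.083][299.111]CVG
I[211.14][268.32]I[187.685]IV[246.077]
FF[238.18]IITAG[273.235]
YEDRIVVR[230.004]
[316.142]TVYCMSIEITA[226.21]IEDI[241.221]
GVI[248.157]NITGYR
IA[128.08]MFTIIE[216.039]GV[215.166]
[278.338]A[234.386]WHVEN[210.973]VNI[210.062]
[265.105]V[213.051][172.098]A[283.126]Y[201.071][210.087][278.104][269.011]RGIVMV[283.117]
[127.983]AG[153.948]ACTGEMGSCG
YSVFCMM[128.12]V
[225.309]SWD[217.039][271.219]C[258.226][218.143][302.82]GMIGSEN
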