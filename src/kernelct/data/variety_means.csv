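variety,BR_pct,moisture_pct,W,L,T,AR,weight_mg,Vg,Ven,Vem,Vc,Vsc,Vemc,Venc,SAg,SAen,SAem,SAc,SSAg,SSAen,SSAem,SSAc,VRen,VRem,VRc,VRsc,VRemc,VRenc,DE,SP
XY335,49.7,11.6,8.05,14.0,4.11,1.73,346,285.9,248.5,26.2,11.2,3.85,3.51,3.80,371.0,699.6,155.2,280.3,1.30,2.80,5.92,26.2,86.9,9.22,3.84,1.34,1.20,1.30,1.278,0.565
M751,57.2,13.4,7.85,14.0,4.21,1.79,356,280.6,241.0,29.8,10.3,4.49,1.58,4.29,409.4,693.6,184.6,226.3,1.46,2.87,6.30,21.4,86.0,10.55,3.65,1.57,0.56,1.53,1.198,0.510
DH618,56.4,11.5,8.62,14.2,4.84,1.65,382,327.8,282.5,34.0,11.0,3.85,3.99,3.15,454.6,788.6,207.0,262.6,1.39,2.79,6.09,24.6,86.2,10.43,3.28,1.20,1.14,0.94,1.175,0.507
KX3564,61.9,12.4,8.36,14.1,4.07,1.69,323,283.7,244.2,26.3,13.9,5.86,2.22,5.79,406.3,777.3,175.4,296.3,1.44,3.21,6.67,21.7,86.1,9.27,4.92,2.10,0.77,2.05,1.140,0.514
KX9384,54.6,12.5,8.89,12.9,4.41,1.46,340,305.5,272.8,24.9,8.64,1.35,2.39,5.03,429.0,722.2,151.0,236.7,1.41,2.66,6.10,27.4,89.3,8.15,2.81,0.44,0.79,1.64,1.177,0.513
LC808,51.6,12.8,8.79,13.8,4.33,1.58,364,295.5,251.2,30.3,14.3,2.70,3.39,8.20,404.8,808.2,176.6,339.3,1.37,3.22,5.85,24.8,85.1,10.26,4.82,0.91,1.15,2.76,1.233,0.530
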