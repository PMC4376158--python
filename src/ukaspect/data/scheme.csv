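label,bone,zone,axial,sagittal,statistic
F2ip,F,2,i,p,mean
F1ip,F,1,i,p,mean
F2ia,F,2,i,a,mean
F1ia,F,1,i,a,max
F2sa,F,2,s,a,max
F1sa,F,1,s,a,max
F1sp,F,1,s,p,mean
F2sp,F,2,s,p,max
P2s,P,2,s,,max
P2i,P,2,i,,max
P1i,P,1,i,,max
P1s,P,1,s,,max
T2sp,T,2,s,p,max
T3sp,T,3,s,p,max
T1sp,T,1,s,p,max
T2sa,T,2,s,a,max
T3sa,T,3,s,a,max
T1sa,T,1,s,a,max
T2ia,T,2,i,a,max
T3ia,T,3,i,a,max
T1ia,T,1,i,a,max
T2ip,T,2,i,p,max
T3ip,T,3,i,p,max
T1ip,T,1,i,p,max
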