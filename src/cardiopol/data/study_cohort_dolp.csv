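subject_id,group,ventricle,thickness_mm,dolp
C1,control,LV,,0.135
C1,control,RV,,0.075
C2,control,LV,,0.11
C2,control,RV,,0.078
C3,control,LV,,0.076
C3,control,RV,,0.076
C4,control,LV,,0.091
C4,control,RV,,0.064
C5,control,LV,,0.066
C5,control,RV,,0.029
C6,control,LV,,0.093
C6,control,RV,,0.066
C7,control,LV,,0.046
C7,control,RV,,0.03
D1,RHD,LV,,0.195
D1,RHD,RV,,0.179
D2,RHD,LV,,0.102
D2,RHD,RV,,0.069
D3,RHD,LV,,0.032
D3,RHD,RV,,0.052
D4,RHD,LV,,0.1
D4,RHD,RV,,0.044
D5,RHD,LV,,0.026
D5,RHD,RV,,0.03
D6,RHD,LV,,0.069
D6,RHD,RV,,0.073
D7,RHD,LV,,0.103
D7,RHD,RV,,0.093
M1,MV,LV,,0.218
M1,MV,RV,,0.157
M2,MV,LV,,0.039
M2,MV,RV,,0.066
M3,MV,LV,,0.035
M3,MV,RV,,0.14
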