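patient_id,polygraph_diagnosis,mobile_odi,polygraph_odi
C1,CSA,22.4,31.0
C2,CSA,18.9,24.5
C3,CSA,30.2,28.7
C4,CSA,7.1,19.8
C5,CSA,11.6,22.3
C6,CSA,3.4,16.2
C7,CSA,9.8,12.4
O1,OSA,25.3,35.1
O2,OSA,17.0,27.9
O3,OSA,21.8,40.6
O4,OSA,12.2,26.4
O5,OSA,5.9,18.1
O6,OSA,10.7,21.5
N1,none,19.5,9.3
N2,none,16.8,4.2
N3,none,23.1,11.7
N4,none,15.6,6.8
N5,none,8.4,3.5
N6,none,2.7,1.9
N7,none,12.9,7.6
N8,none,6.1,10.2
N9,none,4.5,2.8
C8,CSA,,
N10,none,,
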