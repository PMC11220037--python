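0-back:
  a:
    location: 1.140120984246073
    lower: 0.001
    scale: 0.3377961193673724
    upper: 10.0
  p_contam:
    location: -0.09172127175984651
    lower: 0.0
    scale: 0.0863976438126577
    upper: 0.5
  st0:
    location: 0.16291149079744227
    lower: 0.0
    scale: 0.09325924524443686
    upper: 1.0
  t0:
    location: 0.347189803920269
    lower: 0.05
    scale: 0.061715014839538326
    upper: 1.0
  v_lure:
    location: 1.860890269226911
    lower: -10.0
    scale: 1.2664685734413548
    upper: 10.0
  v_novel:
    location: 3.188228136301571
    lower: -10.0
    scale: 1.2071302272063493
    upper: 10.0
  v_target:
    location: 2.5406957885829287
    lower: -10.0
    scale: 1.2783232683358172
    upper: 10.0
  z:
    location: 0.5279265192588435
    lower: 0.1
    scale: 0.12216717564338798
    upper: 0.9
2-back:
  a:
    location: 1.221280903267595
    lower: 0.001
    scale: 0.29787750280898556
    upper: 10.0
  p_contam:
    location: 0.022749790449480816
    lower: 0.0
    scale: 0.06597238917304415
    upper: 0.5
  st0:
    location: 0.19648468840094002
    lower: 0.0
    scale: 0.12116153362358666
    upper: 1.0
  t0:
    location: 0.3967961189497601
    lower: 0.05
    scale: 0.06055884596908069
    upper: 1.0
  v_lure:
    location: 1.0412432024101903
    lower: -10.0
    scale: 1.1148277305669672
    upper: 10.0
  v_novel:
    location: 2.4061185268616763
    lower: -10.0
    scale: 1.124194300711481
    upper: 10.0
  v_target:
    location: 1.7852500474839097
    lower: -10.0
    scale: 1.3129357690717316
    upper: 10.0
  z:
    location: 0.5113048990751063
    lower: 0.1
    scale: 0.11070786110068147
    upper: 0.9
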