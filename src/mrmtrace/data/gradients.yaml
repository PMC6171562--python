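# HPLC gradient programs for the four acquisition methods.
# %B is the organic phase fraction; times in minutes.
pos_underivatized:
  name: pos_underivatized
  buffers: "A: 99.9% H2O / 0.1% formic acid; B: 99.9% methanol / 0.1% formic acid"
  column_temperature_c: 40
  flow_ml_min: 0.4
  timetable:
    - [0, 0]
    - [3, 5]
    - [10, 60]
    - [11, 95]
    - [14, 95]
    - [15, 5]
    - [16, 0]
    - [21, 0]
neg_underivatized:
  name: neg_underivatized
  buffers: "A: 5 mM ammonium acetate in H2O; B: 100% acetonitrile"
  column_temperature_c: 25
  flow_ml_min: 0.4
  timetable:
    - [0, 0]
    - [3, 5]
    - [10, 60]
    - [11, 95]
    - [14, 95]
    - [15, 5]
    - [16, 0]
    - [21, 0]
obha_gradient1:
  name: obha_gradient1
  buffers: "A: 99.9% H2O / 0.1% formic acid; B: 99.9% methanol / 0.1% formic acid"
  column_temperature_c: 40
  flow_ml_min: 0.4
  timetable:
    - [0, 50]
    - [2, 75]
    - [6, 100]
    - [15, 100]
    - [17, 50]
    - [21, 50]
obha_gradient2:
  name: obha_gradient2
  buffers: "A: 99.9% H2O / 0.1% formic acid; B: 99.9% methanol / 0.1% formic acid"
  column_temperature_c: 40
  flow_ml_min: 0.4
  timetable:
    - [0, 50]
    - [2, 65]
    - [12, 90]
    - [12.01, 100]
    - [15, 100]
    - [20, 50]
    - [26, 50]
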