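mpp: 1.0
classes:
- id: 0
  name: BACK
  group: background
  color:
  - 255
  - 255
  - 255
- id: 1
  name: TUMOR
  group: tumor_region
  color:
  - 200
  - 0
  - 0
- id: 2
  name: TU_STROMA
  group: tumor_region
  color:
  - 255
  - 160
  - 120
- id: 3
  name: NECROSIS
  group: tumor_region
  color:
  - 30
  - 30
  - 120
- id: 4
  name: MUCIN
  group: tumor_region
  color:
  - 140
  - 210
  - 240
- id: 5
  name: TLS
  group: benign
  color:
  - 250
  - 220
  - 0
- id: 6
  name: LUNG_BENIGN
  group: benign
  color:
  - 150
  - 220
  - 150
- id: 7
  name: STROMA
  group: benign
  color:
  - 190
  - 190
  - 190
- id: 8
  name: BRONCH
  group: benign
  color:
  - 150
  - 90
  - 40
- id: 9
  name: BLOOD
  group: benign
  color:
  - 255
  - 60
  - 60
- id: 10
  name: GLAND_PERIBR
  group: benign
  color:
  - 90
  - 160
  - 200
- id: 11
  name: CARTIL
  group: benign
  color:
  - 120
  - 120
  - 200
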