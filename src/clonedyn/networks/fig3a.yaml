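name: fig3a
nodes:
- name: HSC
  observed: false
  branch: none
  ancestor: null
  dup: true
  death: true
- name: P1
  observed: false
  branch: none
  ancestor: HSC
  dup: true
  death: true
- name: P2
  observed: false
  branch: none
  ancestor: P1
  dup: true
  death: true
- name: T
  observed: true
  branch: lymphoid
  ancestor: P2
  dup: true
  death: true
- name: B
  observed: true
  branch: lymphoid
  ancestor: P2
  dup: true
  death: true
- name: G
  observed: true
  branch: myeloid
  ancestor: P2
  dup: true
  death: true
edges:
- - HSC
  - P1
- - P1
  - P2
- - P2
  - T
- - P2
  - B
- - P2
  - G
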