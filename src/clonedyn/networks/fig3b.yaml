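name: fig3b
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
  branch: myeloid
  ancestor: P1
  dup: true
  death: true
- name: P3
  observed: false
  branch: lymphoid
  ancestor: P1
  dup: true
  death: true
- name: G
  observed: true
  branch: myeloid
  ancestor: P2
  dup: true
  death: true
- name: M
  observed: true
  branch: myeloid
  ancestor: P2
  dup: true
  death: true
- name: T
  observed: true
  branch: lymphoid
  ancestor: P3
  dup: true
  death: true
- name: B
  observed: true
  branch: lymphoid
  ancestor: P3
  dup: true
  death: true
edges:
- - HSC
  - P1
- - P1
  - P2
- - P1
  - P3
- - P2
  - G
- - P2
  - M
- - P3
  - T
- - P3
  - B
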