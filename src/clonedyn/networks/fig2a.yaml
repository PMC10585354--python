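name: fig2a
nodes:
- name: HSC
  observed: false
  branch: none
  ancestor: null
  dup: true
  death: true
- name: MPP
  observed: false
  branch: none
  ancestor: HSC
  dup: true
  death: true
- name: CMLP
  observed: false
  branch: none
  ancestor: MPP
  dup: true
  death: true
- name: MEP
  observed: false
  branch: myeloid
  ancestor: CMLP
  dup: true
  death: true
- name: GMP
  observed: false
  branch: myeloid
  ancestor: CMLP
  dup: true
  death: true
- name: T
  observed: true
  branch: lymphoid
  ancestor: CMLP
  dup: true
  death: true
- name: B
  observed: true
  branch: lymphoid
  ancestor: CMLP
  dup: true
  death: true
- name: NK
  observed: true
  branch: lymphoid
  ancestor: CMLP
  dup: true
  death: true
- name: G
  observed: true
  branch: myeloid
  ancestor: GMP
  dup: true
  death: true
- name: M
  observed: true
  branch: myeloid
  ancestor: GMP
  dup: true
  death: true
- name: P
  observed: true
  branch: myeloid
  ancestor: MEP
  dup: true
  death: true
- name: ERY
  observed: true
  branch: myeloid
  ancestor: MEP
  dup: true
  death: true
edges:
- - HSC
  - MPP
- - MPP
  - CMLP
- - CMLP
  - T
- - CMLP
  - B
- - CMLP
  - NK
- - CMLP
  - MEP
- - CMLP
  - GMP
- - MEP
  - P
- - MEP
  - ERY
- - GMP
  - G
- - GMP
  - M
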