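graph [
  directed 1
  node [
    id 0
    label "X"
    type "drug"
  ]
  node [
    id 1
    label "Y"
    type "drug"
  ]
  node [
    id 2
    label "A"
    type "go"
  ]
  node [
    id 3
    label "B"
    type "go"
  ]
  node [
    id 4
    label "C"
    type "go"
  ]
  node [
    id 5
    label "D"
    type "go"
  ]
  node [
    id 6
    label "E"
    type "go"
  ]
  node [
    id 7
    label "1"
    type "adr"
  ]
  node [
    id 8
    label "2"
    type "adr"
  ]
  node [
    id 9
    label "3"
    type "adr"
  ]
  node [
    id 10
    label "4"
    type "adr"
  ]
  node [
    id 11
    label "5"
    type "adr"
  ]
  node [
    id 12
    label "6"
    type "adr"
  ]
  edge [
    source 0
    target 2
    weight 1.0
  ]
  edge [
    source 0
    target 3
    weight 1.0
  ]
  edge [
    source 0
    target 4
    weight 1.0
  ]
  edge [
    source 1
    target 4
    weight 1.0
  ]
  edge [
    source 1
    target 5
    weight 1.0
  ]
  edge [
    source 1
    target 6
    weight 1.0
  ]
  edge [
    source 2
    target 7
    weight 1.0
  ]
  edge [
    source 2
    target 8
    weight 1.0
  ]
  edge [
    source 2
    target 9
    weight 1.0
  ]
  edge [
    source 3
    target 11
    weight 1.0
  ]
  edge [
    source 4
    target 10
    weight 1.0
  ]
  edge [
    source 5
    target 11
    weight 1.0
  ]
  edge [
    source 6
    target 12
    weight 1.0
  ]
]
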