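references:
  papain:
    family: L
    synthetic: false
    mature_start: 1
    positions:
      '19': 19
      '23': 23
      '25': 25
      '65': 65
      '67': 67
      '68': 68
      '133': 133
      '157': 157
      '159': 159
      '175': 175
      '205': 205
  syn_cathepsin_L1:
    family: L
    synthetic: true
    mature_start: 61
    positions:
      '19': 79
      '23': 83
      '25': 85
      '65': 125
      '67': 127
      '68': 128
      '133': 193
      '157': 217
      '159': 219
      '175': 235
      '205': 265
  syn_cathepsin_L2:
    family: L
    synthetic: true
    mature_start: 1
    positions:
      '19': 19
      '23': 23
      '25': 25
      '65': 65
      '67': 67
      '68': 68
      '133': 133
      '157': 157
      '159': 159
      '175': 175
      '205': 205
  syn_cathepsin_B:
    family: B
    synthetic: true
    mature_start: 63
    positions:
      '19': 81
      '23': 85
      '25': 87
      '65': 127
      '67': 129
      '68': 130
      '133': 218
      '157': 242
      '159': 244
      '175': 260
      '205': 290
    loop:
      labels_start: 104
      labels_end: 126
      positions:
      - 170
      - 171
      - 172
      - 173
      - 174
      - 175
      - 176
      - 177
      - 178
      - 179
      - 180
      - 181
      - 182
      - 183
      - 184
      - 185
      - 186
      - 187
      - 188
      - 189
      - 190
      - 191
      - 192
      his_pair:
      - 176
      - 177
      his_labels:
      - 110
      - 111
  syn_cathepsin_F:
    family: F
    synthetic: true
    mature_start: 1
    positions:
      '19': 19
      '23': 23
      '25': 25
      '65': 65
      '67': 67
      '68': 68
      '133': 133
      '157': 157
      '159': 159
      '175': 175
      '205': 205
  syn_cathepsin_O:
    family: O
    synthetic: true
    mature_start: 1
    positions:
      '19': 19
      '23': 23
      '25': 25
      '65': 65
      '67': 67
      '68': 68
      '133': 133
      '157': 157
      '159': 159
      '175': 175
      '205': 205
  syn_cathepsin_K:
    family: K
    synthetic: true
    mature_start: 1
    positions:
      '19': 19
      '23': 23
      '25': 25
      '65': 65
      '67': 67
      '68': 68
      '133': 133
      '157': 157
      '159': 159
      '175': 175
      '205': 205
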