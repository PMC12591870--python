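# Stock previous-generation small baseline (comparison row).
name: yolov8s
width: 0.5
depth: 0.33
max_channels: 1024
num_classes: 2
input_size: 640
layers:
  - {kind: conv_bn, out: 64, k: 3, s: 2}
  - {kind: conv_bn, out: 128, k: 3, s: 2}
  - {kind: c2f, out: 128, n: 3}
  - {kind: conv_bn, out: 256, k: 3, s: 2}
  - {kind: c2f, out: 256, n: 6}
  - {kind: conv_bn, out: 512, k: 3, s: 2}
  - {kind: c2f, out: 512, n: 6}
  - {kind: conv_bn, out: 1024, k: 3, s: 2}
  - {kind: c2f, out: 1024, n: 3}
  - {kind: sppf, out: 1024, k: 5}
  - {kind: upsample}
  - {kind: concat, from: [-1, 6]}
  - {kind: c2f, out: 512, n: 3, shortcut: false}
  - {kind: upsample}
  - {kind: concat, from: [-1, 4]}
  - {kind: c2f, out: 256, n: 3, shortcut: false}
  - {kind: conv_bn, out: 256, k: 3, s: 2}
  - {kind: concat, from: [-1, 12]}
  - {kind: c2f, out: 512, n: 3, shortcut: false}
  - {kind: conv_bn, out: 512, k: 3, s: 2}
  - {kind: concat, from: [-1, 9]}
  - {kind: c2f, out: 1024, n: 3, shortcut: false}
  - {kind: detect_legacy, from: [15, 18, 21]}
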