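# Stock small-baseline detector plan (nano scale).
# Nominal channels are scaled by `width` (cap `max_channels`), repeats by `depth`.
name: yolov11s
width: 0.5
depth: 0.5
max_channels: 1024
num_classes: 2
input_size: 640
layers:
  - {kind: conv_bn, out: 64, k: 3, s: 2}          # 0  P1
  - {kind: conv_bn, out: 128, k: 3, s: 2}         # 1  P2
  - {kind: c3k2, out: 256, n: 2, be: 0.25}        # 2
  - {kind: conv_bn, out: 256, k: 3, s: 2}         # 3  P3
  - {kind: c3k2, out: 512, n: 2, be: 0.25}        # 4
  - {kind: conv_bn, out: 512, k: 3, s: 2}         # 5  P4
  - {kind: c3k2, out: 512, n: 2, c3k: true}       # 6
  - {kind: conv_bn, out: 1024, k: 3, s: 2}        # 7  P5
  - {kind: c3k2, out: 1024, n: 2, c3k: true}      # 8
  - {kind: sppf, out: 1024, k: 5}                 # 9
  - {kind: c2psa, out: 1024, n: 2}                # 10
  - {kind: upsample}                              # 11
  - {kind: concat, from: [-1, 6]}                 # 12
  - {kind: c3k2, out: 512, n: 2}                  # 13
  - {kind: upsample}                              # 14
  - {kind: concat, from: [-1, 4]}                 # 15
  - {kind: c3k2, out: 256, n: 2}                  # 16  P3 out
  - {kind: conv_bn, out: 256, k: 3, s: 2}         # 17
  - {kind: concat, from: [-1, 13]}                # 18
  - {kind: c3k2, out: 512, n: 2}                  # 19  P4 out
  - {kind: conv_bn, out: 512, k: 3, s: 2}         # 20
  - {kind: concat, from: [-1, 10]}                # 21
  - {kind: c3k2, out: 1024, n: 2, c3k: true}      # 22  P5 out
  - {kind: detect, from: [16, 19, 22]}            # 23
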