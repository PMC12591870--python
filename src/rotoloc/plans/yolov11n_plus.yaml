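# Lightweight detector: inverted-residual (MIRB) low-level stages and
# universal inverted-bottleneck (MUIB) mid/high-level stages in the
# backbone, pruned cross-stage-partial neck, stock decoupled head.
#
# The layer plan is underdetermined by its published description; the
# printed parameter/FLOP totals of the two scale variants act as
# checksums and pin the block choices recorded here (see docs/methods.md).
# Channels are nominal: actual width = make_divisible(nominal * width, 8).
# "prune: identity" replaces a partial-stage bottleneck by the identity
# path (the cross-stage concat keeps its three branches).
name: yolov11n_plus
width: 0.25
depth: 1.0
max_channels: 1024
num_classes: 2
input_size: 640
layers:
  - {kind: conv_bn, out: 64, k: 3, s: 2}             # 0  P1 stem
  - {kind: mirb, out: 80, k: 3, s: 2, e: 4}          # 1  P2
  - {kind: mirb, out: 80, k: 5, s: 1, e: 2}          # 2
  - {kind: mirb, out: 128, k: 3, s: 2, e: 2}         # 3  P3
  - {kind: mirb, out: 128, k: 3, s: 1, e: 2}         # 4
  - {kind: muib, out: 240, k: 5, s: 2, e: 4}         # 5  P4
  - {kind: muib, out: 240, k: 5, s: 1, e: 2, start_k: 5}   # 6
  - {kind: muib, out: 240, k: 5, s: 1, e: 2, start_k: 5}   # 7
  - {kind: muib, out: 512, k: 5, s: 2, e: 6}         # 8  P5
  - {kind: muib, out: 512, k: 3, s: 1, e: 6}         # 9
  - {kind: muib, out: 512, k: 3, s: 1, e: 6}         # 10
  - {kind: muib, out: 512, k: 3, s: 1, e: 6}         # 11
  - {kind: muib, out: 512, k: 3, s: 1, e: 6}         # 12
  - {kind: sppf, out: 512, k: 5}                     # 13
  - {kind: upsample}                                 # 14
  - {kind: concat, from: [-1, 7]}                    # 15
  - {kind: c3k2, out: 512, n: 1, pruning: identity}  # 16
  - {kind: upsample}                                 # 17
  - {kind: concat, from: [-1, 4]}                    # 18
  - {kind: c3k2, out: 256, n: 1, pruning: identity}  # 19  P3 out
  - {kind: conv_bn, out: 256, k: 3, s: 2}            # 20
  - {kind: concat, from: [-1, 16]}                   # 21
  - {kind: c3k2, out: 512, n: 1, c3k: true}          # 22  P4 out
  - {kind: conv_bn, out: 512, k: 3, s: 2}            # 23
  - {kind: concat, from: [-1, 13]}                   # 24
  - {kind: c3k2, out: 1024, n: 1, c3k: true}         # 25  P5 out
  - {kind: detect, from: [19, 22, 25]}               # 26
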