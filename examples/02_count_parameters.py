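"""Build the four architectures and print their trainable parameter counts.

The joint Interleaved network is smaller than the Alternating and
single-space baselines because its first layer convolves the raw
2-channel input in both streams (2->64 twice) where the others spend a
full 64->64 convolution.
"""

from jointmri import NetworkConfig, build_network, count_parameters

for variant in ("interleaved", "alternating", "frequency", "image"):
    net = build_network(NetworkConfig(variant=variant), rng=0)
    print(f"{variant:>12}: {count_parameters(net):,} trainable parameters")
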