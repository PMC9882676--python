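"""Audit the encoder-decoder data flow at full and desk scale.

Prints every stage's output shape for the dual-view network: the 2D encoder
(representation), the latent reshape + 1x1x1 convolution (transformation),
and the 3D transposed-conv decoder (generation). The element count is
conserved through the reshape — the transformation invents no data.
"""

from surview3d import NetworkScaleConfig

for label, cfg in [
    ("full scale (1024^2 -> 128^3)", NetworkScaleConfig.full_scale()),
    ("desk scale, divisor 8 (128^2 -> 32^3)", NetworkScaleConfig.desk_scale()),
]:
    print(f"\n{label}: {cfg.parameter_count(dual=True):,} parameters (dual view)")
    for stage, shape in cfg.shape_trace(dual=True):
        print(f"  {stage:26s} {' x '.join(str(s) for s in shape)}")
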