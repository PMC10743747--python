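"""Architecture-level contracts that are testable without training.

Three facts about the segmentation networks are pure arithmetic and belong
in code rather than prose:

* the 800x800 wrapper downsamples by two stride-2 blocks to 200x200 and
  upsamples back with two stride-2 transposed convolutions, so any input
  with sides divisible by 4 maps to (H/4, W/4) internally and back to
  (H, W);
* deep-supervision training combines the four intermediate decoder losses
  and the fused output loss as L = 0.25*L1 + 0.25*L2 + 0.5*L3 + 0.75*L4 +
  L_output;
* fine-tuning on a new hospital freezes every encoder-path parameter group
  and leaves decoder groups trainable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

__all__ = ["DEEP_SUPERVISION_WEIGHTS", "WrapperSpec", "ParameterGroup",
           "deep_supervision_loss", "wrapper_shape_check", "freeze_encoder"]

#: (w1, w2, w3, w4, w_output) applied to (L1, L2, L3, L4, L_output)
DEEP_SUPERVISION_WEIGHTS: Tuple[float, ...] = (0.25, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class WrapperSpec:
    """Shape contract of the full-resolution wrapper around the 200x200 core.

    Entry: two blocks of two 3x3 convolutions (stride 2, batch
    normalization, leaky ReLU with 0.01 negative slope), 800 → 400 → 200.
    Exit: two stride-2 transposed convolutions interspersed with two
    encoder-style blocks, 200 → 400 → 800; four output class maps.
    """

    input_side: int = 800
    internal_side: int = 200
    downsample_factor: int = 4
    output_channels: int = 4


def deep_supervision_loss(l1: float, l2: float, l3: float, l4: float,
                          l_output: float) -> float:
    """Weighted deep-supervision loss 0.25*l1 + 0.25*l2 + 0.5*l3 + 0.75*l4 + l_output."""
    terms = (l1, l2, l3, l4, l_output)
    for i, v in enumerate(terms):
        if not (v == v and v >= 0 and v != float("inf")):
            raise ValueError(f"loss term {i + 1} must be finite and >= 0, got {v}")
    return sum(w * v for w, v in zip(DEEP_SUPERVISION_WEIGHTS, terms))


def wrapper_shape_check(input_shape: Tuple[int, int],
                        spec: WrapperSpec = WrapperSpec()) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """(internal_shape, output_shape) for an input of (H, W).

    Two stride-2 halvings require H and W divisible by 4; the output is
    resized back to the input shape.
    """
    h, w = input_shape
    f = spec.downsample_factor
    if h % f or w % f:
        raise ValueError(f"input sides must be divisible by {f}, got {input_shape}")
    return (h // f, w // f), (h, w)


@dataclass(frozen=True)
class ParameterGroup:
    """One named group of network parameters, tagged encoder- or decoder-path."""

    name: str
    path: str  # "encoder" or "decoder"
    n_params: int = 0
    trainable: bool = True


def freeze_encoder(inventory: Sequence[ParameterGroup]) -> List[ParameterGroup]:
    """Freeze every encoder-path group; decoder groups are untouched.

    For the nested (U-Net++-style) variant the encoder is the backbone
    column X[i,0] for all i; callers tag those groups "encoder". Idempotent.
    Raises on groups tagged neither encoder nor decoder.
    """
    out = []
    for g in inventory:
        if g.path not in ("encoder", "decoder"):
            raise ValueError(f"parameter group {g.name!r} has unknown path tag {g.path!r}")
        out.append(replace(g, trainable=False) if g.path == "encoder" else g)
    return out
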