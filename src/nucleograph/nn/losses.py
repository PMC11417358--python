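"""Focal cross-entropy on the two-channel softmax output.

Voxel labelling is heavily imbalanced (most of a map is neither phosphate,
sugar nor base), so plain cross-entropy is dominated by easy negatives.
The focal loss down-weights well-classified points by ``(1 - p_t)^gamma``
and re-balances the classes with ``alpha``:

    L = -mean_t  alpha_t * (1 - p_t)^gamma * log(p_t)

where ``p_t`` is the probability assigned to the true channel and
``alpha_t`` is ``alpha`` for positive voxels, ``1 - alpha`` for negative.
"""

from __future__ import annotations

import numpy as np

from .layers import softmax_channels

FOCAL_ALPHA = 0.25
FOCAL_GAMMA = 2.0
_EPS = 1e-12


def focal_loss(logits: np.ndarray, targets: np.ndarray,
               alpha: float = FOCAL_ALPHA,
               gamma: float = FOCAL_GAMMA) -> tuple[float, np.ndarray]:
    """Mean focal loss and its gradient with respect to the logits.

    Parameters
    ----------
    logits : (N, 2, D, H, W) raw network output; channel 1 is "positive".
    targets : (N, D, H, W) binary ground truth.
    """
    probs = softmax_channels(logits)
    y = np.asarray(targets)
    p_pos = probs[:, 1]
    p_t = np.where(y > 0.5, p_pos, 1.0 - p_pos)
    p_t = np.clip(p_t, _EPS, 1.0)
    a_t = np.where(y > 0.5, alpha, 1.0 - alpha)
    one_minus = 1.0 - p_t
    loss = float(np.mean(-a_t * one_minus ** gamma * np.log(p_t)))

    # dL/dp_t, then through the softmax Jacobian (gradient only flows from
    # the true channel's probability)
    g = a_t * (gamma * one_minus ** np.maximum(gamma - 1.0, 0.0)
               * np.log(p_t) - one_minus ** gamma / p_t)
    n_points = y.size
    true_ch = (y > 0.5).astype(logits.dtype)  # 1 where channel 1 is true
    dlogits = np.empty_like(logits)
    # dp_t/dz_c = p_t * (delta_{c,t} - p_c)
    delta1 = true_ch
    delta0 = 1.0 - true_ch
    dlogits[:, 0] = g * p_t * (delta0 - probs[:, 0])
    dlogits[:, 1] = g * p_t * (delta1 - probs[:, 1])
    dlogits /= n_points
    return loss, dlogits
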