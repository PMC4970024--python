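"""Self-contained simulation experiments built from the library pieces.

These are the desk-scale study emulations: they regenerate the inputs
from a seed, run the method, and return what it measured.  Each is used
both by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .stats import cda_confusion, cda_fit

__all__ = ["weed_height_cda_experiment"]


def weed_height_cda_experiment(
    seed: int = 1,
    n_grass: int = 13,
    n_broadleaf: int = 13,
    n_mixture: int = 10,
    grass_height_range: tuple[float, float] = (0.12, 0.20),
    broadleaf_height_range: tuple[float, float] = (0.02, 0.10),
    p90_ratio: float = 0.9,
) -> dict:
    """Classify weed groups from height features alone, leave-one-out.

    Emulates the field height separations: grass-infested quadrats carry
    a per-sample maximum weed height drawn uniformly from the grass
    range, broadleaf-only quadrats from the much lower broadleaf range,
    and mixtures inherit the grass maximum because the tallest plant in a
    mixed quadrat is a grass.  The 90th-percentile height is taken as a
    fixed fraction of the maximum.  A canonical discriminant model on
    (max, p90) is fitted and every sample is classified by leave-one-out
    nearest centroid in canonical space.

    Returns the confusion matrix plus the percentage of broadleaf-only
    samples recovered as dicots — the decisive cell, since the height gap
    makes dicots the one cleanly separable group while monocots and
    mixtures share the same height signature.
    """
    rng = np.random.default_rng(seed)
    g = rng.uniform(*grass_height_range, size=n_grass)
    b = rng.uniform(*broadleaf_height_range, size=n_broadleaf)
    m = rng.uniform(*grass_height_range, size=n_mixture)
    max_h = np.concatenate([g, b, m])
    labels = np.array(
        ["monocots"] * n_grass + ["dicots"] * n_broadleaf + ["mixture"] * n_mixture
    )
    features = np.column_stack([max_h, p90_ratio * max_h])
    model = cda_fit(features, labels)
    cm = cda_confusion(model, features, labels, scheme="leave_one_out")
    dicot_row = cm.percentages[cm.labels.index("dicots")]
    return {
        "confusion": cm,
        "dicot_recovery_pct": float(dicot_row[cm.labels.index("dicots")]),
        "n_samples": int(len(labels)),
        "n_broadleaf": n_broadleaf,
    }
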