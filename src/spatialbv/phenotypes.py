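"""Phenotype assembly: y = mu + g + h + s + e.

One record per phenotyped cow: her (rescaled) true breeding value, one
herd effect draw shared by herd-mates, the herd's total spatial effect and
an independent residual.  The population mean is 0 in simulation — the
evaluation models carry a free intercept, so a shift is unidentifiable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spatial import SpatialEnvironment


def assemble(phenotyped: pd.DataFrame, spatial_env: SpatialEnvironment,
             herd_var: float = 0.25, resid_var: float = 0.25,
             mu: float = 0.0, seed=None) -> pd.DataFrame:
    """Phenotype records with stored components for later evaluation.

    ``phenotyped`` needs columns id, herd (1-based) and tbv.  Herd effects
    are N(0, herd_var), one draw per herd; residuals N(0, resid_var) per
    animal; the spatial component is the herd's entry of the environment's
    total effect.  Summation order is fixed (g, h, s, e) so the invariant
    y = mu + g + h + s + e holds exactly in floating point.
    """
    rng = np.random.default_rng(seed)
    n_herds = spatial_env.total_effect.shape[0]
    herd_idx = phenotyped["herd"].to_numpy() - 1
    if herd_idx.min() < 0 or herd_idx.max() >= n_herds:
        raise ValueError("animal assigned to a herd with no spatial value")
    herd_effects = rng.standard_normal(n_herds) * np.sqrt(herd_var)
    g = phenotyped["tbv"].to_numpy(dtype=float)
    h = herd_effects[herd_idx]
    s = spatial_env.total_effect[herd_idx]
    e = rng.standard_normal(g.size) * np.sqrt(resid_var)
    return pd.DataFrame({"id": phenotyped["id"].to_numpy(),
                         "herd": phenotyped["herd"].to_numpy(),
                         "y": mu + g + h + s + e,
                         "g": g, "h": h, "s": s, "e": e})


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records[["id", "herd", "y"]].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)
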