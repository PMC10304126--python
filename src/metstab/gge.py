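"""GGE biplot mathematics and the ideal-genotype ranking.

GGE removes the environment main effect from the cell means (each column
centered by its environment mean) and decomposes the remainder — genotype
main effect plus interaction — by SVD.  With genotype-focused singular
value partitioning the genotype coordinates carry the singular values and
environment coordinates are unit-scaled.

The "ideal" genotype lies on the average-environment axis (the direction
of the mean of the environment coordinates) at the largest projection any
real genotype attains: maximal mean performance with zero instability.
Genotypes are ranked by Euclidean distance of their first-two-axis
coordinates to that point, closest first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DegeneracyError, METDataError

__all__ = ["GGEFit", "fit_gge", "ideal_genotype_ranking"]


@dataclass
class GGEFit:
    """Environment-centered SVD with 2-D biplot coordinates."""

    centered: pd.DataFrame          # g x e, columns sum to 0
    singular_values: np.ndarray
    genotype_coords: pd.DataFrame   # g x 2 (axes padded with 0 if rank < 2)
    environment_coords: pd.DataFrame  # e x 2
    explained: np.ndarray           # per retained axis, fractions of total


def fit_gge(means: pd.DataFrame, centering: str = "environment",
            svp: str = "genotype") -> GGEFit:
    """Fit the GGE model to a genotype x environment means table.

    ``centering="environment"`` (the G+GE model) subtracts each column
    mean; no scaling is applied.  ``svp`` controls which side carries the
    singular values ("genotype", "environment" or "symmetric").
    """
    g, e = means.shape
    if g < 3:
        raise METDataError(f"GGE needs at least 3 genotypes, got {g}")
    y = means.to_numpy(dtype=float)
    if centering == "environment":
        z = y - y.mean(axis=0, keepdims=True)
    elif centering == "double":
        z = (y - y.mean(axis=0, keepdims=True)
             - y.mean(axis=1, keepdims=True) + y.mean())
    else:
        raise METDataError(f"unknown centering {centering!r}")
    if not np.any(np.abs(z) > 1e-12 * max(np.abs(y).max(), 1.0)):
        raise DegeneracyError("no genotypic signal after centering")

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # reproducible axis orientation: largest |genotype loading| positive
    for k in range(len(s)):
        i = int(np.argmax(np.abs(u[:, k])))
        if u[i, k] < 0:
            u[:, k] *= -1.0
            vt[k] *= -1.0
    n_axes = min(2, len(s))
    if svp == "genotype":
        gco, eco = u[:, :n_axes] * s[:n_axes], vt[:n_axes].T
    elif svp == "environment":
        gco, eco = u[:, :n_axes], vt[:n_axes].T * s[:n_axes]
    elif svp == "symmetric":
        root = np.sqrt(s[:n_axes])
        gco, eco = u[:, :n_axes] * root, vt[:n_axes].T * root
    else:
        raise METDataError(f"unknown svp {svp!r}")
    if n_axes < 2:  # single-environment edge case: pad a zero second axis
        gco = np.hstack([gco, np.zeros((g, 1))])
        eco = np.hstack([eco, np.zeros((e, 1))])
    tot = float((s ** 2).sum())
    return GGEFit(
        centered=pd.DataFrame(z, index=means.index, columns=means.columns),
        singular_values=s,
        genotype_coords=pd.DataFrame(gco, index=means.index,
                                     columns=["axis1", "axis2"]),
        environment_coords=pd.DataFrame(eco, index=means.columns,
                                        columns=["axis1", "axis2"]),
        explained=s[:2] ** 2 / tot if tot > 0 else np.zeros(2),
    )


def ideal_genotype_ranking(fit: GGEFit) -> pd.DataFrame:
    """Rank genotypes by distance to the ideal genotype, closest first.

    Returns a DataFrame indexed by genotype with the axis-1/2 coordinates,
    the projection onto the average-environment axis, the distance to the
    ideal point, and the 1-based rank.
    """
    env = fit.environment_coords.to_numpy()
    aec = env.mean(axis=0)
    norm = float(np.linalg.norm(aec))
    if norm <= 1e-12:
        raise DegeneracyError(
            "average-environment direction is degenerate (zero mean)")
    aec_unit = aec / norm
    coords = fit.genotype_coords.to_numpy()
    proj = coords @ aec_unit
    ideal = aec_unit * proj.max()
    dist = np.linalg.norm(coords - ideal, axis=1)
    out = pd.DataFrame({
        "axis1": coords[:, 0],
        "axis2": coords[:, 1],
        "aec_projection": proj,
        "distance": dist,
    }, index=fit.genotype_coords.index)
    out = out.sort_values("distance", kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
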