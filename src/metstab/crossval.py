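"""Replicate-holdout cross-validation of BLUP and the AMMI family.

Each resample splits every environment's blocks into a training set (all
but one replicate, e.g. two of three) and a validation set (the remaining
complete replicate), refits every candidate model on the training plots
only, predicts each (genotype, environment) cell, and scores the root
mean square prediction difference

    RMSPD = sqrt( mean over validation plots of (predicted - observed)^2 ).

Candidates are AMMI0 (additive) through AMMIF (all multiplicative axes)
plus the BLUP model, whose cell prediction is the shrunken genotype mean
deviation plus the fixed environment deviation plus the shrunken GE
entry.  Variance components are re-estimated inside every training
resample.  Smaller mean RMSPD over resamples means better predictive
accuracy; among AMMI members of comparable accuracy the fewest-axis model
is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import METDataError, METDataset

__all__ = ["CVResult", "split_train_validate", "rmspd", "cv_compare"]


@dataclass
class CVResult:
    """Per-resample RMSPD for every candidate model."""

    rmspd: pd.DataFrame     # rows = resamples, columns = models
    seed: int

    @property
    def n_resamples(self) -> int:
        return len(self.rmspd)

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation of RMSPD per model, best first."""
        out = pd.DataFrame({"mean": self.rmspd.mean(axis=0),
                            "sd": self.rmspd.std(axis=0, ddof=1)})
        return out.sort_values("mean", kind="stable")

    def best_model(self) -> str:
        """Model with the smallest mean RMSPD."""
        return str(self.rmspd.mean(axis=0).idxmin())

    def chosen_ammi(self, comparability: float = 0.01) -> str:
        """Simplest AMMI member within ``comparability`` of the best AMMI.

        Among AMMI members whose mean RMSPD is within the given fraction
        of the best AMMI member's, the one with the fewest axes wins.
        """
        means = self.rmspd.mean(axis=0)
        ammi = means[[m for m in means.index if m.startswith("AMMI")]]
        best = float(ammi.min())
        ok = ammi[ammi <= best * (1.0 + comparability)]
        return str(ok.index[0])  # columns are ordered AMMI0..AMMIF


def split_train_validate(data: METDataset, seed: int | np.random.Generator
                         ) -> tuple[METDataset, METDataset]:
    """Hold one complete replicate per environment out for validation.

    Within each environment one block label is chosen uniformly at
    random; its plots form the validation set and the remaining blocks
    the training set.  Deterministic under a fixed seed.
    """
    if data.r < 2:
        raise METDataError("cross-validation needs at least 2 replicates")
    data.require_balanced("cross-validation")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    reps = np.asarray(data.replicates)
    held = {env: reps[rng.integers(len(reps))] for env in data.environments}
    df = data.records
    is_val = df.apply(
        lambda row: row["replicate"] == held[row["environment"]], axis=1)
    return METDataset(df[~is_val]), METDataset(df[is_val])


def rmspd(predicted, observed) -> float:
    """Root mean square difference between predictions and held-out plots."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size == 0:
        raise METDataError("empty validation set")
    if p.size != o.size:
        raise METDataError(
            f"prediction/observation length mismatch: {p.size} vs {o.size}")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def cv_compare(data: METDataset, n_resamples: int = 1000,
               seed: int = 0) -> CVResult:
    """Compare AMMI0..AMMIF and BLUP by replicate-holdout RMSPD.

    Returns one RMSPD per (model, resample); the whole run is
    deterministic under the seed.
    """
    if n_resamples < 1:
        raise METDataError("n_resamples must be >= 1")
    data.require_balanced("cross-validation")
    if data.r < 2:
        raise METDataError("cross-validation needs at least 2 replicates")
    y = data.to_array()                      # (g, e, r)
    g, e, r = y.shape
    p = min(g - 1, e - 1)
    names = (["AMMI0"] + [f"AMMI{k}" for k in range(1, p)] + ["AMMIF"]
             + ["BLUP"])
    rng = np.random.default_rng(seed)
    env_idx = np.arange(e)
    all_reps = np.arange(r)
    out = np.empty((n_resamples, len(names)))

    for it in range(n_resamples):
        val = rng.integers(0, r, size=e)
        train_idx = np.array([all_reps[all_reps != v] for v in val])  # e,r-1
        tr = y[:, env_idx[:, None], train_idx]                       # g,e,r-1
        obs = y[:, env_idx, val]                                     # g,e
        rt = r - 1

        cell = tr.mean(axis=2)
        gen_m = cell.mean(axis=1)
        env_m = cell.mean(axis=0)
        mu = cell.mean()
        z = cell - gen_m[:, None] - env_m[None, :] + mu

        # training-plot mean squares for the BLUP variance components
        rep_m = tr.mean(axis=0)                                      # e,r-1
        ss_total = ((tr - mu) ** 2).sum()
        ss_env = g * rt * ((env_m - mu) ** 2).sum()
        ss_rep = g * ((rep_m - env_m[:, None]) ** 2).sum()
        ss_gen = e * rt * ((gen_m - mu) ** 2).sum()
        ss_ge = rt * (z ** 2).sum()
        ss_res = max(ss_total - ss_env - ss_rep - ss_gen - ss_ge, 0.0)
        df_res = e * (g - 1) * (rt - 1)
        ms_res = ss_res / df_res if df_res > 0 else 0.0
        ms_ge = ss_ge / ((g - 1) * (e - 1))
        ms_g = ss_gen / (g - 1)
        s2_res = ms_res
        s2_ge = max((ms_ge - ms_res) / rt, 0.0)
        s2_g = max((ms_g - ms_ge) / (e * rt), 0.0)

        u, s, vt = np.linalg.svd(z, full_matrices=False)
        additive = mu + (gen_m - mu)[:, None] + (env_m - mu)[None, :]
        comps = np.einsum("k,gk,ke->kge", s[:p], u[:, :p], vt[:p])
        cum = np.cumsum(comps, axis=0)

        col = 0
        out[it, col] = np.sqrt(np.mean((additive - obs) ** 2))
        col += 1
        for k in range(1, p + 1):
            pred = additive + cum[k - 1]
            out[it, col] = np.sqrt(np.mean((pred - obs) ** 2))
            col += 1

        w_den = s2_g + s2_ge / e + s2_res / (e * rt)
        w = s2_g / w_den if w_den > 0 else 0.0
        s_den = s2_ge + s2_res / rt
        sh = s2_ge / s_den if s_den > 0 else 0.0
        pred_blup = (mu + w * (gen_m - mu)[:, None]
                     + (env_m - mu)[None, :] + sh * z)
        out[it, col] = np.sqrt(np.mean((pred_blup - obs) ** 2))

    return CVResult(rmspd=pd.DataFrame(out, columns=names), seed=int(seed))
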