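"""Structural compactness: the terminal-Ca index and its resampling nulls.

For a single-chain model the compactness index is

    Ic = d / N,

where d is the Euclidean distance (angstroms) between the Ca atoms of the
first and last residues and N the residue count; smaller Ic means a more
compact fold.  The significance of a group's mean Ic is judged against
empirical distributions of means of ``sample_size`` proteins drawn from a
reference pool — unrestricted, size-matched, or Met-content-matched —
repeated ``reps`` times (lower tail: the claim under test is "more
compact").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NullMode = Literal["unrestricted", "size_matched", "met_matched"]


@dataclass
class CompactnessRecord:
    accession: str
    d: float
    N: int

    @property
    def Ic(self) -> float:
        return self.d / self.N


@dataclass
class NullIcDistribution:
    mode: NullMode
    sample_size: int
    reps: int
    means: np.ndarray
    seed: int
    observed_mean: float
    p_value: float
    p_is_bound: bool  # True when no null mean fell at/below the observed

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "sample_size": self.sample_size,
            "reps": self.reps,
            "null_mean": float(np.mean(self.means)),
            "null_sd": float(np.std(self.means)),
            "observed_mean": self.observed_mean,
            "p_value": self.p_value,
            "p_is_bound": self.p_is_bound,
            "seed": self.seed,
        }


def compactness_index(structure_file: str | Path, accession: str | None = None) -> CompactnessRecord:
    """Ic from a PDB/mmCIF file: distance between the first and last
    Ca-bearing residues of the first chain, over the chain's residue count.

    Raises ValueError when fewer than two residues carry a Ca atom.
    """
    st = gemmi.read_structure(str(structure_file))
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError(f"{structure_file}: no model/chain")
    chain = st[0][0]  # AlphaFold-style single chain
    ca_pos = []
    for res in chain:
        atom = res.find_atom("CA", "*")
        if atom is not None:
            ca_pos.append(atom.pos)
    if len(ca_pos) < 2:
        raise ValueError(f"{structure_file}: fewer than two residues with a CA atom")
    d = ca_pos[0].dist(ca_pos[-1])
    return CompactnessRecord(accession or st.name or Path(structure_file).stem, float(d), len(chain))


def compactness_table(
    structure_files: dict[str, str | Path]
) -> tuple[pd.DataFrame, list[str]]:
    """Ic for a set of accession -> structure-file mappings; unreadable or
    Ca-less structures are skipped with a logged reason."""
    rows, skipped = [], []
    for acc, path in structure_files.items():
        try:
            rec = compactness_index(path, accession=acc)
        except (ValueError, RuntimeError) as exc:
            logger.warning("skipping %s: %s", acc, exc)
            skipped.append(acc)
            continue
        rows.append({"accession": acc, "d": rec.d, "N": rec.N, "Ic": rec.Ic})
    return pd.DataFrame(rows), skipped


def _matched_draw(
    rng: np.random.Generator,
    targets: np.ndarray,
    pool_values: np.ndarray,
    rel_tol: float | None,
    abs_tol: float | None,
) -> np.ndarray:
    """One matched sample without replacement: for each target value pick a
    distinct pool member within tolerance, widening the tolerance stepwise
    (x2, logged) when no unused match exists."""
    chosen = np.full(len(targets), -1, dtype=int)
    used = np.zeros(len(pool_values), dtype=bool)
    order = rng.permutation(len(targets))
    for t in order:
        tol_r, tol_a = rel_tol, abs_tol
        while True:
            if rel_tol is not None:
                lo, hi = targets[t] * (1 - tol_r), targets[t] * (1 + tol_r)
            else:
                lo, hi = targets[t] - tol_a, targets[t] + tol_a
            ok = np.flatnonzero(~used & (pool_values >= lo) & (pool_values <= hi))
            if len(ok):
                pick = int(rng.choice(ok))
                chosen[t] = pick
                used[pick] = True
                break
            if rel_tol is not None:
                tol_r *= 2
            else:
                tol_a = (tol_a or 1e-6) * 2
            logger.debug("widening matching tolerance for target %s", targets[t])
    return chosen


def null_ic(
    pool: pd.DataFrame,
    observed_mean: float,
    mode: NullMode = "unrestricted",
    sample_size: int = 49,
    reps: int = 10_000,
    seed: int = 0,
    targets: pd.DataFrame | None = None,
    tol_len: float = 0.10,
    tol_met: float = 0.005,
    alternative: Literal["less", "two-sided"] = "less",
) -> NullIcDistribution:
    """Empirical distribution of mean Ic over resampled protein sets.

    ``pool`` needs columns Ic plus length (size matching) or met_freq (Met
    matching); ``targets`` supplies the matched group's lengths/frequencies
    (defaults to a ``sample_size`` subset requirement).  p is the fraction
    of null means <= observed (lower tail), reported as a "< 1/reps" bound
    when the tail is empty.
    """
    if len(pool) <= sample_size:
        raise ValueError("pool must be larger than sample_size")
    rng = np.random.default_rng(seed)
    ic = pool["Ic"].to_numpy()
    means = np.empty(reps)
    if mode == "unrestricted":
        for r in range(reps):
            means[r] = ic[rng.choice(len(ic), size=sample_size, replace=False)].mean()
    else:
        col = "length" if mode == "size_matched" else "met_freq"
        if targets is None:
            raise ValueError(f"mode {mode!r} needs a targets table with column {col!r}")
        tvals = targets[col].to_numpy()
        if len(tvals) != sample_size:
            raise ValueError("targets must have exactly sample_size rows")
        pvals = pool[col].to_numpy()
        rel_tol = tol_len if mode == "size_matched" else None
        abs_tol = None if mode == "size_matched" else tol_met
        for r in range(reps):
            idx = _matched_draw(rng, tvals, pvals, rel_tol, abs_tol)
            means[r] = ic[idx].mean()
    tie_eps = 1e-12 * max(1.0, abs(observed_mean))  # fp ties count as hits
    if alternative == "less":
        hits = int(np.sum(means <= observed_mean + tie_eps))
    else:
        null_mean = means.mean()
        hits = int(np.sum(np.abs(means - null_mean) >= abs(observed_mean - null_mean)))
    bound = hits == 0
    p = (hits / reps) if not bound else 1.0 / reps
    return NullIcDistribution(mode, sample_size, reps, means, seed, observed_mean, p, bound)
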