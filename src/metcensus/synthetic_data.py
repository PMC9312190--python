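"""Synthetic proteomes, structures and GO annotations for pipeline testing.

The generators emulate the statistical structure the census analysis
assumes about real data:

* a proteome of 100–5,000-residue proteins with i.i.d. ~2% methionine,
  a planted subpopulation carrying a local Met cluster (and optionally a
  prion-composition segment), and a subpopulation with no Met beyond the
  initiator;
* single-chain, CA-only structures (extended or random-walk back-bones);
* GAF 2.2 annotation files in which within-group term overlap exceeds
  between-group overlap, planting positive label assortativity.

Everything is deterministic under the spec seed: the same spec regenerates
byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import gemmi
import numpy as np
import pandas as pd

from .proteome_io import ProteinRecord, write_proteome
from .tables import AMINO_ACIDS, EMISSION_TABLES, table_with_met_weight

logger = logging.getLogger(__name__)

_AA = np.array(list(AMINO_ACIDS))
_MET_IDX = AMINO_ACIDS.index("M")


@dataclass
class ClusterSpec:
    """A planted Met cluster: ``n_met_in_window`` methionines forced into a
    uniformly placed window of ``window_len`` residues (never over position 1)."""

    window_len: int
    n_met_in_window: int

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("cluster_spec.window_len must be >= 1")
        if not 0 < self.n_met_in_window <= self.window_len:
            raise ValueError("cluster_spec.n_met_in_window must be in (0, window_len]")


@dataclass
class PrldSpec:
    """A planted prion-composition segment drawn i.i.d. from a named
    emission table (with an optional Met re-weighting)."""

    segment_len: int
    emission_table_id: str = "prion"
    met_weight: float | None = 0.2

    def __post_init__(self) -> None:
        if self.segment_len < 1:
            raise ValueError("prld_spec.segment_len must be >= 1")
        if self.emission_table_id not in EMISSION_TABLES:
            raise ValueError(
                f"prld_spec.emission_table_id unknown: {self.emission_table_id!r}"
            )


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic proteome."""

    n_proteins: int = 1000
    length_law: tuple = ("lognormal", 6.1, 0.55)  # ~450-residue median
    met_freq: float = 0.02
    planted_fraction: float = 0.0
    zero_met_fraction: float = 0.0
    cluster_spec: ClusterSpec | None = None
    prld_spec: PrldSpec | None = None
    initiator_met: bool = True
    seed: int = 0

    MIN_LEN = 100
    MAX_LEN = 5000

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0.0 <= self.met_freq <= 1.0:
            raise ValueError("met_freq must be in [0, 1]")
        for name in ("planted_fraction", "zero_met_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        law = self.length_law
        if law[0] == "fixed":
            if not self.MIN_LEN <= law[1] <= self.MAX_LEN:
                raise ValueError("fixed length must be within [100, 5000]")
        elif law[0] != "lognormal":
            raise ValueError(f"unknown length_law: {law[0]!r}")


def _draw_lengths(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    law = spec.length_law
    if law[0] == "fixed":
        return np.full(spec.n_proteins, int(law[1]), dtype=int)
    mu, sigma = law[1], law[2]
    lengths = np.empty(spec.n_proteins, dtype=int)
    have = 0
    while have < spec.n_proteins:  # rejection-truncate to [100, 5000]
        draw = rng.lognormal(mu, sigma, size=spec.n_proteins).astype(int)
        keep = draw[(draw >= spec.MIN_LEN) & (draw <= spec.MAX_LEN)]
        take = min(len(keep), spec.n_proteins - have)
        lengths[have : have + take] = keep[:take]
        have += take
    return lengths


def _background_sequence(
    length: int, met_freq: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. residues: Met with probability met_freq, the rest drawn from
    the bundled background table (Met entry excluded, renormalised)."""
    non_met = np.delete(EMISSION_TABLES["background"], _MET_IDX)
    non_met = non_met / non_met.sum()
    aa_non_met = np.delete(_AA, _MET_IDX)
    seq = rng.choice(aa_non_met, size=length, p=non_met)
    is_met = rng.random(length) < met_freq
    seq[is_met] = "M"
    return seq


def generate_proteome(
    spec: SyntheticSpec, fasta_path: str | Path | None = None
) -> list[ProteinRecord]:
    """Generate a synthetic proteome (and optionally write it as FASTA).

    Proteins are assigned, in order: the first ``planted_fraction`` receive
    the planted cluster/segment, the next ``zero_met_fraction`` carry no Met
    beyond the initiator, and the remainder are plain background.  Accessions
    encode the group (``SYNP*`` planted, ``SYNZ*`` zero-Met, ``SYNB*``
    background).
    """
    rng = np.random.default_rng(spec.seed)
    lengths = _draw_lengths(spec, rng)
    n_planted = int(round(spec.planted_fraction * spec.n_proteins))
    n_zero = int(round(spec.zero_met_fraction * spec.n_proteins))
    if n_planted + n_zero > spec.n_proteins:
        raise ValueError("planted_fraction + zero_met_fraction exceed 1")

    records: list[ProteinRecord] = []
    for i, L in enumerate(lengths):
        planted = i < n_planted
        zero = n_planted <= i < n_planted + n_zero
        seq = _background_sequence(int(L), 0.0 if zero else spec.met_freq, rng)
        if planted:
            seq = _plant(seq, spec, rng)
        if spec.initiator_met:
            seq[0] = "M"
        tag = "SYNP" if planted else ("SYNZ" if zero else "SYNB")
        records.append(ProteinRecord(f"{tag}{i:05d}", "".join(seq)))
    if fasta_path is not None:
        write_proteome(records, fasta_path)
    return records


def _plant(seq: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    L = len(seq)
    if spec.prld_spec is not None:
        ps = spec.prld_spec
        if ps.segment_len > L - 1:
            raise ValueError("prld segment longer than protein body")
        start = int(rng.integers(1, L - ps.segment_len + 1))  # 0-based, skips pos 1
        seg = _segment_from_table(ps.segment_len, ps.emission_table_id, ps.met_weight, rng)
        seq[start : start + ps.segment_len] = seg
    if spec.cluster_spec is not None:
        cs = spec.cluster_spec
        if cs.window_len > L - 1:
            raise ValueError("cluster window longer than protein body")
        start = int(rng.integers(1, L - cs.window_len + 1))
        idx = rng.choice(cs.window_len, size=cs.n_met_in_window, replace=False)
        seq[start + idx] = "M"
    return seq


def _segment_from_table(
    length: int, table_id: str, met_weight: float | None, rng: np.random.Generator
) -> np.ndarray:
    if met_weight is None:
        p = EMISSION_TABLES[table_id]
    else:
        p = table_with_met_weight(table_id, met_weight)
    return rng.choice(_AA, size=length, p=p)


def generate_prld_segment(
    length: int,
    emission_table_id: str = "prion",
    seed: int = 0,
    met_weight: float | None = None,
) -> str:
    """i.i.d. sequence from a named bundled emission table."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if emission_table_id not in EMISSION_TABLES:
        raise KeyError(f"unknown emission table: {emission_table_id!r}")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    return "".join(_segment_from_table(length, emission_table_id, met_weight, rng))


StructureMode = Literal["extended", "random_walk"]


def generate_structure(
    n_residues: int,
    mode: StructureMode = "extended",
    bond_len: float = 3.8,
    seed: int = 0,
    pdb_path: str | Path | None = None,
    name: str = "SYNTH",
) -> gemmi.Structure:
    """Single-model, single-chain CA-only trace.

    ``extended`` places the CA atoms collinearly at ``bond_len`` spacing;
    ``random_walk`` takes successive steps of ``bond_len`` in uniformly
    random directions (a freely jointed chain).
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if mode == "extended":
        coords = np.zeros((n_residues, 3))
        coords[:, 0] = bond_len * np.arange(n_residues)
    elif mode == "random_walk":
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(n_residues - 1, 3))
        steps *= bond_len / np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    else:
        raise ValueError(f"unknown structure mode: {mode!r}")

    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (x, y, z) in enumerate(coords, start=1):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if pdb_path is not None:
        st.write_pdb(str(pdb_path))
    return st


GAF_COLUMNS = 17


def generate_go_annotations(
    n_red: int,
    n_blue: int,
    terms_per_protein: int,
    within_overlap: float,
    between_overlap: float,
    seed: int = 0,
    gaf_path: str | Path | None = None,
    noise: float = 0.0,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Two labelled protein groups with controlled GO-term overlap.

    Each protein's term set is assembled from three pools: a globally shared
    pool (``between_overlap`` of the terms, common to every protein), a
    group-core pool (so same-group pairs share ``within_overlap`` of their
    terms) and protein-private terms.  With within=1/between=0 same-group
    pairs are identical and cross-group pairs disjoint.

    ``noise`` independently replaces each pooled term with a fresh private
    one at the given probability, spreading pairwise Jaccard values around
    their pool-determined expectations (real annotation sets are not
    block-identical); at 0 the pools are used exactly.

    Returns (accession -> term set, label table) and optionally writes a
    GAF 2.2 file.
    """
    for name, v in (("within_overlap", within_overlap), ("between_overlap", between_overlap)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if between_overlap > within_overlap:
        raise ValueError("within_overlap must be >= between_overlap")
    t = terms_per_protein
    n_shared = int(round(between_overlap * t))
    n_core = int(round(within_overlap * t)) - n_shared
    n_private = t - n_shared - n_core
    if n_private < 0:
        raise ValueError("overlap fractions imply more core terms than terms_per_protein")
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")

    rng = np.random.default_rng(seed)
    counter = iter(range(1, 10**7))

    def fresh_terms(k: int) -> list[str]:
        return [f"GO:{next(counter):07d}" for _ in range(k)]

    shared = fresh_terms(n_shared)
    cores = {"MR": fresh_terms(n_core), "NonMR": fresh_terms(n_core)}
    annotations: dict[str, set[str]] = {}
    labels = []
    for label, n, tag in (("MR", n_red, "RED"), ("NonMR", n_blue, "BLU")):
        for i in range(n):
            acc = f"{tag}{i:04d}"
            pooled = [
                t for t in shared + cores[label]
                if noise == 0.0 or rng.random() >= noise
            ]
            dropped = n_shared + n_core - len(pooled)
            annotations[acc] = set(pooled) | set(fresh_terms(n_private + dropped))
            labels.append({"accession": acc, "label": label})
    label_table = pd.DataFrame(labels)
    if gaf_path is not None:
        write_gaf(annotations, gaf_path)
    return annotations, label_table


def write_gaf(annotations: dict[str, set[str]], gaf_path: str | Path) -> None:
    """Write an annotation map as minimal valid GAF 2.2 rows."""
    with open(gaf_path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for acc in sorted(annotations):
            for term in sorted(annotations[acc]):
                row = [""] * GAF_COLUMNS
                row[0] = "UniProtKB"
                row[1] = acc
                row[2] = acc
                row[3] = "involved_in"
                row[4] = term
                row[5] = "GO_REF:0000000"
                row[6] = "IEA"
                row[8] = "P"
                row[11] = "protein"
                row[12] = "taxon:9606"
                row[13] = "20220629"
                row[14] = "SynthGen"
                fh.write("\t".join(row) + "\n")


def write_label_table(label_table: pd.DataFrame, path: str | Path) -> None:
    label_table.to_csv(path, sep="\t", index=False)
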