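"""Kimura two-parameter distances and Ks-based divergence dating.

The molecular clock used throughout is ``Time = Ks / (2 mu)`` with
``mu`` in substitutions/site/year: 6.5e-9 for dating LTR-retrotransposon
insertions from their terminal-repeat divergence, and 6.1e-9 for
whole-genome-duplication and lineage-divergence dating from gene-pair Ks
values.  For LTRs, "Ks" is the K2P nucleotide distance between the 5'
and 3' terminal repeats of one element (a neutral, non-coding distance,
not a codon-model Ks); gene-pair Ks values are accepted precomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

#: substitution rate (per site per year) for LTR insertion dating
MU_LTR = 6.5e-9
#: substitution rate for WGD / lineage-divergence dating
MU_DIVERGENCE = 6.1e-9

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_VALID = set("ACGT")


class SaturationError(ValueError):
    """K2P distance undefined: too much divergence for the correction."""


@dataclass
class AlignedPair:
    """Two equal-length gapped nucleotide sequences."""

    seq_a: str
    seq_b: str
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        alphabet = set("ACGTN-")
        bad = (set(self.seq_a) | set(self.seq_b)) - alphabet
        if bad:
            raise ValueError(f"unexpected characters in alignment: {bad}")


@dataclass
class DatingResult:
    """Substitution proportions, K2P distance and the derived age."""

    p_transition: float
    q_transversion: float
    sites_compared: int
    k2p: float
    mu: float
    time_years: float
    label: str = ""


def count_substitutions(pair: AlignedPair) -> tuple[float, float, int]:
    """Transition/transversion proportions over comparable columns.

    Columns with a gap or N in either sequence are excluded pairwise
    (the EMBOSS distmat convention).  Returns (P, Q, sites_compared).
    """
    ts = tv = n = 0
    for a, b in zip(pair.seq_a, pair.seq_b):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a == b:
            continue
        if frozenset((a, b)) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable (gap/N-free) columns in alignment")
    return ts / n, tv / n, n


def k2p_distance(P: float, Q: float) -> float:
    """Kimura (1980) two-parameter distance.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q); raises
    :class:`SaturationError` when either log argument is <= 0.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"substitution proportions P={P:g}, Q={Q:g} are saturated; "
            "K2P distance is undefined")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def ks_to_time(ks: float, mu: float) -> float:
    """Molecular-clock conversion Time = Ks / (2 mu), in years."""
    if ks < 0:
        raise ValueError("ks must be >= 0")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return ks / (2.0 * mu)


def date_ltr_pair(pair: AlignedPair, mu: float = MU_LTR,
                  label: str = "") -> DatingResult:
    """Date one LTR element from its terminal-repeat alignment."""
    P, Q, n = count_substitutions(pair)
    d = k2p_distance(P, Q)
    return DatingResult(p_transition=P, q_transversion=Q, sites_compared=n,
                        k2p=d, mu=mu, time_years=ks_to_time(d, mu),
                        label=label)


def date_ks_table(ks: pd.DataFrame | dict, mu: float = MU_DIVERGENCE
                  ) -> pd.DataFrame:
    """Convert a (pair_id, ks) table to ages.

    Accepts a DataFrame with columns ``pair_id`` and ``ks`` (or a plain
    mapping) and returns it with ``time_years`` and ``time_mya`` added.
    """
    if isinstance(ks, dict):
        ks = pd.DataFrame({"pair_id": list(ks), "ks": list(ks.values())})
    out = ks.copy()
    out["time_years"] = [ks_to_time(float(v), mu) for v in out["ks"]]
    out["time_mya"] = out["time_years"] / 1e6
    return out


def read_pair_fasta(path: str | Path) -> AlignedPair:
    """Read a two-record aligned FASTA into an :class:`AlignedPair`."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned records, "
                         f"found {len(records)}")
    return AlignedPair(seq_a=str(records[0].seq), seq_b=str(records[1].seq),
                       label_a=records[0].id, label_b=records[1].id)


def write_pair_fasta(pair: AlignedPair, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pair.label_a}\n{pair.seq_a}\n")
        fh.write(f">{pair.label_b}\n{pair.seq_b}\n")


def iter_pair_fastas(directory: str | Path) -> Iterator[tuple[str, AlignedPair]]:
    """Yield (stem, pair) for every .fa/.fasta file in a directory."""
    directory = Path(directory)
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in (".fa", ".fasta", ".fna"):
            yield p.stem, read_pair_fasta(p)


def ks_histogram(values, bin_width: float = 0.005,
                 mu: Optional[float] = None) -> pd.DataFrame:
    """Bin Ks (or K2P) values for peak inspection.

    Returns a DataFrame (bin_lo, bin_hi, count[, time_mya_mid]) — peak
    calling is left to the user.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "count"])
    n_bins = max(1, int(np.ceil(v.max() / bin_width)))
    counts, edges = np.histogram(v, bins=n_bins, range=(0, n_bins * bin_width))
    out = pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                        "count": counts})
    if mu is not None:
        out["time_mya_mid"] = (out.bin_lo + out.bin_hi) / 2.0 / (2 * mu) / 1e6
    return out
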