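"""Compound-grouped partitioning into training / validation / test sets.

Spectral libraries hold many spectra per molecule (different collision
energies, instruments).  Random splitting at the spectrum level leaks
compound identity between sets and inflates apparent accuracy, so the split
is done at the *compound* level: all spectra of one molecule land in exactly
one set.  Because spectra-per-compound is heavily skewed, compounds are
shuffled and assigned greedily to the set with the largest remaining
spectrum-count deficit, so spectrum-level fractions approximate the targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

SET_NAMES = ("train", "val", "test")


@dataclass
class SplitAssignment:
    """Record- and compound-level set assignment plus the seed used."""

    record_to_set: dict[str, str]
    compound_to_set: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int
    spectrum_counts: dict[str, int] = field(default_factory=dict)

    def records_in(self, subset: str, records: Sequence) -> list:
        return [r for r in records if self.record_to_set[r.record_id] == subset]

    def write(self, record_path: str | Path, compound_path: str | Path) -> None:
        with open(record_path, "w") as fh:
            fh.write(f"# seed={self.seed}\trecord_id\tsubset\n")
            for rid, s in self.record_to_set.items():
                fh.write(f"{rid}\t{s}\n")
        with open(compound_path, "w") as fh:
            fh.write(f"# seed={self.seed}\tcompound_id\tsubset\n")
            for cid, s in self.compound_to_set.items():
                fh.write(f"{cid}\t{s}\n")


def group_split(
    records: Sequence,
    fractions: tuple[float, float, float] = (0.72, 0.15, 0.13),
    seed: int = 0,
) -> SplitAssignment:
    """Shuffle compounds under ``seed`` and assign them greedily.

    At each step the compound (with all its spectra) goes to the set whose
    spectrum-count deficit (target share of the total minus spectra already
    assigned) is largest; ties resolve in (train, val, test) order.  With one
    spectrum per compound this reduces to the largest-remainder apportionment
    and hits the target counts exactly.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    compound_counts: dict[str, int] = {}
    for rec in records:
        if not rec.compound_id:
            raise ValueError(f"record {rec.record_id} lacks a compound_id")
        compound_counts[rec.compound_id] = compound_counts.get(rec.compound_id, 0) + 1
    compounds = sorted(compound_counts)
    if len(compounds) < 3:
        raise ValueError(f"need at least 3 compounds, got {len(compounds)}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(compounds))
    total = len(records)
    targets = np.array(fractions) * total
    assigned = np.zeros(3)
    compound_to_set: dict[str, str] = {}
    for idx in order:
        cid = compounds[idx]
        deficits = targets - assigned
        s = int(np.argmax(deficits))  # argmax keeps first max: train > val > test
        compound_to_set[cid] = SET_NAMES[s]
        assigned[s] += compound_counts[cid]

    record_to_set = {r.record_id: compound_to_set[r.compound_id] for r in records}
    counts = {s: int((np.array(list(record_to_set.values())) == s).sum()) for s in SET_NAMES}
    return SplitAssignment(
        record_to_set=record_to_set,
        compound_to_set=compound_to_set,
        fractions=tuple(fractions),
        seed=seed,
        spectrum_counts=counts,
    )
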