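"""MACCS substructure-key fingerprints and Jaccard–Tanimoto similarity.

A molecule is encoded as a 166-bit binary vector: bit *t* is set iff the
*t*-th MACCS substructural pattern occurs in the structure.  The RDKit key
definitions emit 167 positions with position 0 unused; position 0 is dropped
here so fingerprints are exactly 166 bits, with array index *t* holding
MACCS key *t + 1*.

Similarity between two fingerprints is the Jaccard–Tanimoto index
``a / (a + b + c)`` over shared (a) and exclusive (b, c) 1-bits.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

N_BITS = 166


def maccs(smiles: str) -> np.ndarray:
    """166-bit MACCS-key fingerprint of a structure.

    Raises ``ValueError`` (naming the offending string) when the SMILES does
    not parse.  Deterministic: identical canonical structures give identical
    bits.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import MACCSkeys

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    arr = np.zeros(N_BITS, dtype=np.uint8)
    for b in bv.GetOnBits():
        if b >= 1:
            arr[b - 1] = 1
    return arr


def _validate_fp(fp: np.ndarray) -> np.ndarray:
    fp = np.asarray(fp)
    if fp.ndim != 1:
        raise ValueError("fingerprint must be 1-D")
    return fp


def similarity_terms(fp_true: np.ndarray, fp_pred: np.ndarray) -> tuple[int, int, int]:
    """(a, b, c): shared 1-bits, 1-in-true-only, 1-in-pred-only."""
    fp_true, fp_pred = _validate_fp(fp_true), _validate_fp(fp_pred)
    if fp_true.shape != fp_pred.shape:
        raise ValueError(
            f"fingerprint length mismatch: {fp_true.shape} vs {fp_pred.shape}"
        )
    t = fp_true.astype(bool)
    p = fp_pred.astype(bool)
    a = int(np.sum(t & p))
    b = int(np.sum(t & ~p))
    c = int(np.sum(~t & p))
    return a, b, c


def jt(fp_true: np.ndarray, fp_pred: np.ndarray) -> float:
    """Jaccard–Tanimoto similarity a/(a+b+c) in [0, 1].

    Two all-zero fingerprints are identical vectors and score 1.0 by
    convention.
    """
    a, b, c = similarity_terms(fp_true, fp_pred)
    if a + b + c == 0:
        return 1.0
    return a / (a + b + c)


def jt_matrix(true_fps: np.ndarray, pred_fps: np.ndarray) -> np.ndarray:
    """Row-wise JT between two aligned (n, bits) binary matrices."""
    t = np.asarray(true_fps, dtype=bool)
    p = np.asarray(pred_fps, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("shape mismatch")
    a = (t & p).sum(axis=1)
    union = (t | p).sum(axis=1)
    out = np.ones(len(t), dtype=float)
    nz = union > 0
    out[nz] = a[nz] / union[nz]
    return out


def random_baseline(
    fp_true: np.ndarray, n_random: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """JT of ``fp_true`` against random fingerprints with the same number of
    active bits (uniformly chosen positions).

    This is the degenerate-knowledge benchmark: a predictor that knows only
    the active-bit fraction of the true fingerprint.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    fp_true = _validate_fp(fp_true)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_bits = fp_true.size
    k = int(fp_true.sum())
    out = np.empty(n_random)
    for i in range(n_random):
        rand = np.zeros(n_bits, dtype=np.uint8)
        if k:
            rand[rng.choice(n_bits, size=k, replace=False)] = 1
        out[i] = jt(fp_true, rand)
    return out


# --------------------------------------------------------------------------
# fingerprint tables (compound_id + 166 {0,1} columns, tab-separated)


def write_fingerprints(fps: Mapping[str, np.ndarray], path: str | Path) -> None:
    n_bits = len(next(iter(fps.values()))) if fps else N_BITS
    with open(path, "w") as fh:
        fh.write("compound_id\t" + "\t".join(f"bit{i+1}" for i in range(n_bits)) + "\n")
        for cid in fps:
            bits = "\t".join(str(int(b)) for b in fps[cid])
            fh.write(f"{cid}\t{bits}\n")


def read_fingerprints(path: str | Path) -> dict[str, np.ndarray]:
    fps: dict[str, np.ndarray] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            fps[parts[0]] = np.array([int(x) for x in parts[1:]], dtype=np.uint8)
    return fps


def read_structures(path: str | Path) -> dict[str, str]:
    """Read a tab-separated structure list (compound_id, SMILES)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.lower().startswith("compound_id"):
                continue
            cid, smiles = line.split("\t")[:2]
            out[cid.strip()] = smiles.strip()
    return out


def fingerprints_from_structures(path: str | Path) -> dict[str, np.ndarray]:
    """MACCS fingerprints for every structure in a (compound_id, SMILES)
    table; an unparseable SMILES raises, naming the compound."""
    fps: dict[str, np.ndarray] = {}
    for cid, smiles in read_structures(path).items():
        try:
            fps[cid] = maccs(smiles)
        except ValueError as exc:
            raise ValueError(f"compound {cid}: {exc}") from exc
    return fps


def fingerprints_for_records(
    records: Sequence, fps: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Stack per-record true fingerprints (rows aligned with ``records``)."""
    return np.vstack([fps[rec.compound_id] for rec in records])
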