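"""Foreground/background conserved-pattern detection in an alignment.

Given a multiple sequence alignment whose rows are split into a foreground
set (e.g. one channel subfamily) and a background set (the remaining
homologs), each column is scored for foreground-specific conservation with a
binomial log-likelihood-ratio contrast: with k_F of n_F foreground and k_B
of n_B background residues matching a candidate residue set R, and
pseudocount a,

    p_hat = (k_F + a) / (n_F + 2a),    q = (k_B + a) / (n_B + 2a)
    score = max(0, k_F ln(p_hat/q) + (n_F - k_F) ln((1-p_hat)/(1-q)))

The residue set is grown greedily from the most frequent foreground residue
while the score increases.  Significance comes from a label-permutation null
of each column's maximal score (shared seed across columns), with
Benjamini-Hochberg FDR across columns.  Selected positions are mapped to
reference-sequence numbering (count of non-gap reference residues up to the
column).  This is a pattern-contrast analogue in the spirit of Bayesian
partitioning with pattern selection, not a re-implementation of it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .simulate import AMINO_ACIDS

__all__ = [
    "PatternParams",
    "PatternPosition",
    "column_contrast_score",
    "select_pattern_positions",
    "map_to_reference",
    "two_level_analysis",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CHARS = set("-.")


@dataclass(frozen=True)
class PatternParams:
    pseudocount: float = 1.0
    n_permutations: int = 5000
    fdr: float = 0.01
    seed: int = 0
    exact: bool = False  # enumerate all label assignments (tiny alignments)

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not self.exact and self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


@dataclass(frozen=True)
class PatternPosition:
    column: int  # 1-based alignment column
    residue_set: str  # sorted residue letters
    score: float
    p_value: float
    fdr: float
    reference_residue: tuple[str, int]  # (letter or "ref-gap", number)


def column_contrast_score(
    residues: Sequence[str],
    labels: Sequence[str],
    residue_set: Iterable[str],
    pseudocount: float = 1.0,
) -> float:
    """Contrast score of one column for an explicit residue set.

    ``labels`` are 'foreground'/'background' per row; gap characters are
    excluded from the counts.  Raises if either side is empty after gap
    removal.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    rset = set(residue_set)
    if not rset:
        raise ValueError("residue set must be non-empty")
    k_f = n_f = k_b = n_b = 0
    for r, lab in zip(residues, labels):
        if r in GAP_CHARS:
            continue
        if lab == "foreground":
            n_f += 1
            k_f += r in rset
        else:
            n_b += 1
            k_b += r in rset
    if n_f == 0 or n_b == 0:
        raise ValueError("empty foreground or background after gap removal")
    return _score_from_counts(k_f, n_f, k_b, n_b, pseudocount)


def _score_from_counts(k_f, n_f, k_b, n_b, a: float) -> float:
    p_hat = (k_f + a) / (n_f + 2 * a)
    q = (k_b + a) / (n_b + 2 * a)
    s = k_f * math.log(p_hat / q) + (n_f - k_f) * math.log((1 - p_hat) / (1 - q))
    return max(0.0, s)


def _greedy_scores(
    kf_sorted: np.ndarray, kc_sorted: np.ndarray, n_f: np.ndarray, n_b: np.ndarray, a: float
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy stop along residue prefixes, vectorised over permutations.

    ``kf_sorted``: (P, 20) foreground match counts with residues ordered by
    descending foreground frequency per permutation; ``kc_sorted`` the
    matching total column counts.  Returns (score at greedy stop, stop size).
    The greedy rule adds residues while the score strictly increases.
    """
    KF = np.cumsum(kf_sorted, axis=1)
    KB = np.cumsum(kc_sorted - kf_sorted, axis=1)
    n_f = n_f.reshape(-1, 1)
    n_b = n_b.reshape(-1, 1)
    p_hat = (KF + a) / (n_f + 2 * a)
    q = (KB + a) / (n_b + 2 * a)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = KF * np.log(p_hat / q) + (n_f - KF) * np.log((1 - p_hat) / (1 - q))
    S = np.maximum(np.nan_to_num(S, nan=0.0, posinf=0.0, neginf=0.0), 0.0)
    # greedy stop: last index of the initial strictly-increasing run
    increasing = np.diff(S, axis=1) > 0
    if increasing.shape[1] == 0:
        stop = np.zeros(S.shape[0], dtype=int)
    else:
        first_flat = np.argmin(increasing, axis=1)  # first non-increase
        all_inc = increasing.all(axis=1)
        stop = np.where(all_inc, S.shape[1] - 1, first_flat)
    scores = S[np.arange(S.shape[0]), stop]
    return scores, stop


def _encode_alignment(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    ids = list(alignment)
    width = {len(s) for s in alignment.values()}
    if len(width) > 1:
        raise ValueError("alignment rows differ in length")
    L = width.pop() if width else 0
    mat = np.full((len(ids), L), -1, dtype=np.int8)  # -1 = gap/unknown
    for i, sid in enumerate(ids):
        for j, ch in enumerate(alignment[sid].upper()):
            mat[i, j] = _AA_INDEX.get(ch, -1)
    return ids, mat


def _label_vector(ids: Sequence[str], labels: Mapping[str, str]) -> np.ndarray:
    lv = np.zeros(len(ids), dtype=bool)
    for i, sid in enumerate(ids):
        lab = labels.get(sid)
        if lab not in ("foreground", "background"):
            raise ValueError(f"sequence {sid!r} lacks a foreground/background label")
        lv[i] = lab == "foreground"
    if lv.sum() < 2 or (~lv).sum() < 2:
        raise ValueError("need at least 2 sequences per label")
    return lv


def select_pattern_positions(
    alignment: Mapping[str, str],
    labels: Mapping[str, str],
    params: PatternParams | None = None,
    reference_id: str | None = None,
) -> list[PatternPosition]:
    """Columns with significant foreground-specific conservation.

    Per column the residue set is grown greedily (see module docstring) and
    the greedy-stop score is tested against a label-permutation null built
    from a single seeded batch of permutations shared by all columns; the
    same greedy procedure is applied inside every permutation.  BH-FDR is
    computed across all scorable columns and positions below ``params.fdr``
    are returned sorted by column.  ``reference_id`` (default: first
    foreground sequence) sets the numbering reference.
    """
    params = params or PatternParams()
    ids, mat = _encode_alignment(alignment)
    if mat.shape[1] == 0:
        return []
    is_fg = _label_vector(ids, labels)
    if reference_id is None:
        reference_id = next(sid for sid in ids if labels[sid] == "foreground")
    elif reference_id not in alignment:
        raise KeyError(f"reference {reference_id!r} not in alignment")

    n_seq, L = mat.shape
    if params.exact:
        combos = list(itertools.combinations(range(n_seq), int(is_fg.sum())))
        perms = np.zeros((len(combos), n_seq), dtype=bool)
        for p, combo in enumerate(combos):
            perms[p, list(combo)] = True
    else:
        rng = np.random.default_rng(params.seed)
        perms = np.empty((params.n_permutations, n_seq), dtype=bool)
        for p in range(params.n_permutations):
            perms[p] = is_fg[rng.permutation(n_seq)]

    columns: list[int] = []
    obs_scores: list[float] = []
    obs_sets: list[str] = []
    pvals: list[float] = []
    a = params.pseudocount
    for c in range(L):
        col = mat[:, c]
        present = col >= 0
        if not present.any():
            continue
        fg_here = is_fg & present
        bg_here = (~is_fg) & present
        if fg_here.sum() == 0 or bg_here.sum() == 0:
            continue  # column skipped: one side is all gaps
        onehot = np.zeros((n_seq, 20))
        onehot[present, col[present]] = 1.0
        kc = onehot.sum(axis=0)  # total count per residue (shared)

        # observed greedy score and residue set
        kf_obs = onehot[is_fg].sum(axis=0)
        order = np.lexsort((np.arange(20), -kf_obs))
        s_obs, stop_obs = _greedy_scores(
            kf_obs[order][None, :],
            kc[order][None, :],
            np.array([fg_here.sum()]),
            np.array([bg_here.sum()]),
            a,
        )
        score = float(s_obs[0])
        residue_set = "".join(sorted(AMINO_ACIDS[i] for i in order[: int(stop_obs[0]) + 1]))

        # permutation null of the same statistic
        kf_perm = perms[:, :, None] * onehot[None, :, :]
        kf_perm = kf_perm.sum(axis=1)  # (P, 20)
        nf_perm = (perms & present).sum(axis=1)
        nb_perm = (~perms & present).sum(axis=1)
        ok = (nf_perm > 0) & (nb_perm > 0)
        order_perm = np.argsort(-kf_perm, axis=1, kind="stable")
        kf_sorted = np.take_along_axis(kf_perm, order_perm, axis=1)
        kc_sorted = np.take_along_axis(
            np.broadcast_to(kc, kf_perm.shape), order_perm, axis=1
        )
        null_scores, _ = _greedy_scores(kf_sorted, kc_sorted, nf_perm, nb_perm, a)
        null_scores = null_scores[ok]
        if params.exact:
            p = float((null_scores >= score - 1e-12).sum()) / len(null_scores)
        else:
            p = (1.0 + float((null_scores >= score - 1e-12).sum())) / (
                len(null_scores) + 1.0
            )
        columns.append(c + 1)
        obs_scores.append(score)
        obs_sets.append(residue_set)
        pvals.append(p)

    if not columns:
        return []
    _, fdrs, _, _ = multipletests(np.array(pvals), method="fdr_bh")
    out = []
    for col, score, rset, p, f in zip(columns, obs_scores, obs_sets, pvals, fdrs):
        if f < params.fdr:
            out.append(
                PatternPosition(
                    column=col,
                    residue_set=rset,
                    score=score,
                    p_value=float(p),
                    fdr=float(f),
                    reference_residue=map_to_reference(alignment, reference_id, col),
                )
            )
    out.sort(key=lambda pp: pp.column)
    return out


def map_to_reference(
    alignment: Mapping[str, str], reference_id: str, column: int
) -> tuple[str, int]:
    """Map a 1-based alignment column to reference-sequence numbering.

    The number is the count of non-gap reference residues from column 1
    through the given column; where the reference is gapped the letter is
    reported as ``"ref-gap"`` with the preceding number.
    """
    ref = alignment[reference_id]
    if not 1 <= column <= len(ref):
        raise IndexError(f"column {column} out of range 1..{len(ref)}")
    prefix = ref[:column]
    number = sum(1 for ch in prefix if ch not in GAP_CHARS)
    letter = ref[column - 1]
    if letter in GAP_CHARS:
        return ("ref-gap", number)
    return (letter, number)


def two_level_analysis(
    alignment: Mapping[str, str],
    labels: Mapping[str, str],
    partition: Mapping[str, Sequence[str]],
    subclade: str,
    params: PatternParams | None = None,
    reference_id: str | None = None,
) -> dict[str, list[PatternPosition]]:
    """Family-wide vs clade-specific pattern tiers.

    ``labels`` mark the family ('foreground') against an outgroup
    ('background'); ``partition`` splits the family's sequence ids into
    subfamily groups, of which ``subclade`` names the focal one.  Two passes
    of :func:`select_pattern_positions` are run: the whole family against
    the outgroup (family-wide patterns), and the focal sub-clade against the
    remaining family members (clade-specific patterns).  Columns appearing
    in both tiers are flagged under ``"overlap"``.
    """
    params = params or PatternParams()
    family_ids = [sid for sid in alignment if labels.get(sid) == "foreground"]
    assigned = [sid for group in partition.values() for sid in group]
    if sorted(assigned) != sorted(family_ids):
        raise ValueError(
            "partition must assign every family sequence to exactly one group"
        )
    if subclade not in partition:
        raise KeyError(f"unknown sub-clade {subclade!r}")

    family_wide = select_pattern_positions(alignment, labels, params, reference_id)

    sub_ids = set(partition[subclade])
    rest = [sid for sid in family_ids if sid not in sub_ids]
    if rest:
        sub_alignment = {sid: alignment[sid] for sid in family_ids}
        sub_labels = {
            sid: "foreground" if sid in sub_ids else "background"
            for sid in family_ids
        }
        ref = reference_id if reference_id in sub_alignment else None
        clade_specific = select_pattern_positions(
            sub_alignment, sub_labels, params, ref
        )
    else:  # partition == whole family: the clade pass degenerates
        clade_specific = family_wide
    family_cols = {p.column for p in family_wide}
    overlap = [p for p in clade_specific if p.column in family_cols]
    return {
        "family_wide": family_wide,
        "clade_specific": clade_specific,
        "overlap": overlap,
    }


def column_frequencies(
    alignment: Mapping[str, str], labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-column foreground/background residue frequencies (logo data).

    Returns a tidy frame (column, label, residue, frequency); gaps are
    excluded from the denominators.
    """
    ids, mat = _encode_alignment(alignment)
    is_fg = _label_vector(ids, labels)
    rows = []
    for c in range(mat.shape[1]):
        col = mat[:, c]
        for name, mask in (("foreground", is_fg), ("background", ~is_fg)):
            sub = col[mask & (col >= 0)]
            total = len(sub)
            if total == 0:
                continue
            counts = np.bincount(sub, minlength=20)
            for i in np.nonzero(counts)[0]:
                rows.append(
                    {
                        "column": c + 1,
                        "label": name,
                        "residue": AMINO_ACIDS[i],
                        "frequency": counts[i] / total,
                    }
                )
    return pd.DataFrame(rows, columns=["column", "label", "residue", "frequency"])


def write_patterns_tsv(positions: Iterable[PatternPosition], path) -> None:
    rows = [
        {
            "column": p.column,
            "residue_set": p.residue_set,
            "score": p.score,
            "p_value": p.p_value,
            "fdr": p.fdr,
            "reference_residue": f"{p.reference_residue[0]}{p.reference_residue[1]}",
        }
        for p in positions
    ]
    pd.DataFrame(
        rows, columns=["column", "residue_set", "score", "p_value", "fdr", "reference_residue"]
    ).to_csv(path, sep="\t", index=False)
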