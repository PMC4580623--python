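"""Benchmark evaluation mathematics.

Two evaluation procedures are implemented.  Specificity enrichment: for a
pair of designed sequence sets (native vs non-native ligand), every observed
mutation gets a percent enrichment PE = difference in percent occurrence
between the two sets, and mutations are ranked by descending PE.  Profile
similarity: per-position amino-acid distributions of designed sequences are
compared to natural binding-site alignments via 1 minus the Jensen-Shannon
divergence (equal mixture weights, base-2 logarithms, so the similarity
spans [0, 1]).  Sequence entropy uses a base-20 logarithm so a uniform
distribution over the 20 amino acids has entropy 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import fisher_exact, ttest_rel

from . import chem

AA_ORDER = chem.CANONICAL_AAS  # alphabetical one-letter codes


# ---------------------------------------------------------------------------
# Benchmark 1: percent enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRow:
    position: object
    from_aa: str
    to_aa: str
    pct_native: float
    pct_nonnative: float
    PE: float
    rank: int = 0
    percentile: float = 0.0

    @property
    def correct(self) -> bool:
        return self.PE > 0


def _occurrence(seqs, col: int, aa: str) -> float:
    return 100.0 * sum(1 for s in seqs if s[col] == aa) / len(seqs)


def enrichment_analysis(
    native_seqs,
    nonnative_seqs,
    direction: str = "wt2mut",
    reference_seq: str | None = None,
    positions=None,
):
    """Percent-enrichment table for all mutations observed in either set.

    `native_seqs` / `nonnative_seqs` are lists of equal-length strings over
    the design positions.  `reference_seq` supplies the starting residue per
    column (default: first native sequence).  PE(WT->MUT) = %non-native -
    %native; PE(MUT->WT) flips the sign.  Ranks are assigned over all
    candidates pooled across positions, sorted by descending PE (ties broken
    by position then amino acid), and percentile = 100 * (N - rank + 1) / N.
    """
    native = list(native_seqs)
    nonnative = list(nonnative_seqs)
    if not native or not nonnative:
        raise ValueError("sequence sets must be nonempty")
    ncol = len(native[0])
    if any(len(s) != ncol for s in native + nonnative):
        raise ValueError("sequences have inconsistent lengths")
    if direction not in ("wt2mut", "mut2wt"):
        raise ValueError("direction must be 'wt2mut' or 'mut2wt'")
    ref = reference_seq if reference_seq is not None else native[0]
    labels = list(positions) if positions is not None else list(range(ncol))

    rows = []
    for col in range(ncol):
        observed = sorted({s[col] for s in native} | {s[col] for s in nonnative})
        for aa in observed:
            if aa == ref[col]:
                continue
            pn = _occurrence(native, col, aa)
            pnn = _occurrence(nonnative, col, aa)
            pe = pnn - pn if direction == "wt2mut" else pn - pnn
            rows.append(EnrichmentRow(labels[col], ref[col], aa, pn, pnn, pe))
    rows.sort(key=lambda r: (-r.PE, str(r.position), r.to_aa))
    n = len(rows)
    for i, r in enumerate(rows, start=1):
        r.rank = i
        r.percentile = 100.0 * (n - i + 1) / n
    return rows


def enrichment_table(rows):
    """Enrichment rows as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "position": [str(r.position) for r in rows],
            "from": [r.from_aa for r in rows],
            "to": [r.to_aa for r in rows],
            "pct_native": [r.pct_native for r in rows],
            "pct_nonnative": [r.pct_nonnative for r in rows],
            "PE": [r.PE for r in rows],
            "rank": [r.rank for r in rows],
            "percentile": [r.percentile for r in rows],
            "correct": [r.correct for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# Benchmark 2: profiles, similarity, entropy
# ---------------------------------------------------------------------------

@dataclass
class PositionProfile:
    position: object
    p: np.ndarray  # distribution over AA_ORDER, sums to 1

    def __post_init__(self):
        self.p = np.asarray(self.p, float)
        if self.p.shape != (20,):
            raise ValueError("profile must be a 20-vector")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("profile must be a normalized distribution")

    @property
    def entropy(self) -> float:
        return sequence_entropy(self)


def build_profiles(seqs, pseudocount: float = 0.0, positions=None):
    """Per-column amino-acid distributions of an aligned sequence set.

    Columns containing gap characters ('-' or '.') are dropped with a
    warning; other non-canonical characters are excluded from the counts of
    their column.  Returns a list of PositionProfile whose ``position``
    labels are the retained column labels.
    """
    seqs = [s.upper() for s in seqs]
    if not seqs:
        raise ValueError("no sequences")
    ncol = len(seqs[0])
    if any(len(s) != ncol for s in seqs):
        raise ValueError("sequences have inconsistent lengths")
    labels = list(positions) if positions is not None else list(range(ncol))
    aa_index = {aa: i for i, aa in enumerate(AA_ORDER)}
    profiles = []
    dropped = []
    for col in range(ncol):
        column = [s[col] for s in seqs]
        if any(c in "-." for c in column):
            dropped.append(labels[col])
            continue
        counts = np.zeros(20)
        for c in column:
            if c in aa_index:
                counts[aa_index[c]] += 1
        counts += pseudocount
        total = counts.sum()
        if total == 0:
            dropped.append(labels[col])
            continue
        profiles.append(PositionProfile(labels[col], counts / total))
    if dropped:
        warnings.warn(f"dropped {len(dropped)} gapped/empty alignment columns: {dropped}")
    return profiles


def profile_similarity(p: PositionProfile, q: PositionProfile) -> float:
    """1 - Jensen-Shannon divergence (equal weights, base-2 logs), in [0, 1]."""
    js = float(jensenshannon(p.p, q.p, base=2) ** 2)
    if math.isnan(js):  # identical distributions can yield 0/0 in the sqrt form
        js = 0.0
    return 1.0 - min(1.0, max(0.0, js))


def sequence_entropy(p: PositionProfile) -> float:
    """H = -sum_x P_x log20 P_x, with 0 log 0 := 0; uniform over 20 gives 1."""
    v = p.p[p.p > 0]
    return float(-(v * (np.log(v) / np.log(20.0))).sum())


def uniform_null_similarity(natural_profiles):
    """Similarity of each natural profile to the uniform distribution over 20."""
    uniform = PositionProfile("uniform", np.full(20, 1 / 20))
    return [profile_similarity(p, uniform) for p in natural_profiles]


def entropy_tertiles(natural_profiles, values=None):
    """Split positions into low/medium/high natural-entropy thirds.

    Sizes differ by at most one; any remainder goes to the lower groups.
    Ties are resolved by stable sort order.  Returns a dict with group name
    -> list of (position, value) pairs; `values` defaults to the entropies.
    """
    profiles = list(natural_profiles)
    if len(profiles) < 3:
        raise ValueError("need at least 3 positions for tertiles")
    vals = list(values) if values is not None else [p.entropy for p in profiles]
    order = sorted(range(len(profiles)), key=lambda i: profiles[i].entropy)
    n = len(profiles)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if k < rem else 0) for k in range(3)]  # remainder to lower groups
    groups = {"low": [], "medium": [], "high": []}
    names = ["low", "medium", "high"]
    start = 0
    for name, size in zip(names, sizes):
        for i in order[start : start + size]:
            groups[name].append((profiles[i].position, vals[i]))
        start += size
    return groups


def frequency_matrix(profiles):
    """Position x amino-acid frequency DataFrame (sequence-logo input)."""
    import pandas as pd

    return pd.DataFrame(
        [p.p for p in profiles],
        index=[p.position for p in profiles],
        columns=list(AA_ORDER),
    )


# ---------------------------------------------------------------------------
# Diagnostics and significance
# ---------------------------------------------------------------------------

def design_diagnostics(trace):
    """(glycine fraction over unique sequences' design positions, acceptance ratio)."""
    seqs = trace.sequences
    total = sum(len(s) for s in seqs)
    gly = sum(s.count("G") for s in seqs)
    frac = gly / total if total else 0.0
    return frac, trace.acceptance_ratio


def fisher_correctness_pvalue(table) -> float:
    """Two-sided Fisher's exact test on a 2x2 correct/incorrect count table."""
    t = np.asarray(table, int)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("degenerate table with a zero margin; p = 1")
        return 1.0
    return float(fisher_exact(t, alternative="two-sided")[1])


def paired_similarity_pvalue(a, b) -> float:
    """Paired two-tailed t-test on per-position profile-similarity vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = a - b
    if np.allclose(diff, diff[0]) and np.isclose(diff.std(), 0.0):
        warnings.warn("zero-variance differences; p = 1")
        return 1.0
    return float(ttest_rel(a, b).pvalue)


def significance_tests(correct_table=None, paired_a=None, paired_b=None):
    """Convenience wrapper returning the requested p-values as a dict."""
    out = {}
    if correct_table is not None:
        out["fisher_p"] = fisher_correctness_pvalue(correct_table)
    if paired_a is not None and paired_b is not None:
        out["paired_t_p"] = paired_similarity_pvalue(paired_a, paired_b)
    return out


# ---------------------------------------------------------------------------
# Structural comparison
# ---------------------------------------------------------------------------

def rmsd_report(model_pose, reference_pose, positions):
    """Heavy-atom side-chain RMSD at selected positions after superposition.

    The model is superposed onto the reference using backbone N/CA/C/O atoms
    of all residues outside the selection; per-position RMSDs are computed
    over side-chain heavy atoms with matching names (a residue-identity
    mismatch compares the common atoms and warns).
    """
    from .geometry import kabsch

    sel = {tuple(p) for p in positions}
    mob, ref = [], []
    for res in model_pose.residues:
        if res.key in sel or not reference_pose.has_residue(res.key):
            continue
        other = reference_pose.residue(res.key)
        for name in chem.BACKBONE_ATOMS:
            if name in res.backbone and name in other.backbone:
                mob.append(res.backbone[name].coords)
                ref.append(other.backbone[name].coords)
    R, t, _ = kabsch(np.array(mob), np.array(ref))
    out = {}
    for key in sorted(sel):
        res = model_pose.residue(key)
        other = reference_pose.residue(key)
        if res.aa != other.aa:
            warnings.warn(f"residue identity mismatch at {key}: {res.aa} vs {other.aa}")
        names_m = {a.name: a.coords for a in res.sidechain if a.is_heavy}
        names_r = {a.name: a.coords for a in other.sidechain if a.is_heavy}
        common = sorted(set(names_m) & set(names_r))
        if not common:
            out[key] = 0.0
            continue
        m = np.array([names_m[n] for n in common]) @ R.T + t
        r = np.array([names_r[n] for n in common])
        out[key] = float(np.sqrt(np.mean(np.sum((m - r) ** 2, axis=1))))
    return out
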