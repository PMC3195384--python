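"""Nei–Gojobori (1986) dN/dS statistics, K2P distance and the Z-test of
positive selection.

The unweighted NG86 method counts, for every codon, the expected numbers of
synonymous (s) and nonsynonymous (n) sites from its nine single-base mutants
(s + n = 3), and classifies observed differences between two codons by
averaging over all orderings of single-base steps connecting them.  Pairwise
proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits with the
one-parameter Jukes–Cantor formula d = -(3/4)·ln(1 - 4p/3); nucleotide
divergence uses the Kimura two-parameter distance that separates transition
(P) and transversion (Q) proportions.

Panel-level dN, dS and d are means over all unordered sequence pairs, with
standard errors from a codon-column (nucleotide-column for K2P) bootstrap.
Positive selection is tested one-tailed with Z = (dN - dS)/SE(dN - dS),
bootstrap variances treated as independent.

Conventions (the classic NG86 choices): single-base changes that create stop
codons count as nonsynonymous in site counting; pathways through stop codons
are discarded when averaging differences, falling back to all pathways if
none is stop-free; codon sites containing a gap, an N, or an observed stop in
either sequence are excluded pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.stats import norm

from .errors import (
    DegenerateVarianceError,
    NoDataError,
    SaturationError,
    UndefinedCodonError,
)
from .seq_io import GENETIC_CODE, AlleleSet

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
PURINES = {"A", "G"}

STATISTICS = ("dN", "dS", "d_k2p")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonSiteCounts:
    """Expected synonymous and nonsynonymous site fractions of one codon."""

    syn_sites: float
    nonsyn_sites: float


@dataclass(frozen=True)
class PairwiseDifferences:
    """Pathway-averaged synonymous/nonsynonymous differences between codons."""

    syn_diffs: float
    nonsyn_diffs: float
    compared_codons: int = 1


@dataclass(frozen=True)
class SubstitutionEstimate:
    """A mean pairwise distance with its bootstrap standard error."""

    estimate: float
    std_error: float
    replicates: int
    seed: int


@dataclass(frozen=True)
class SelectionTest:
    """Result of the one-tailed Z-test of positive selection (dN > dS)."""

    dn: SubstitutionEstimate
    ds: SubstitutionEstimate
    ratio: float | None
    z_stat: float
    p_value: float


# ---------------------------------------------------------------------------
# per-codon primitives
# ---------------------------------------------------------------------------

def _is_sense(codon: str) -> bool:
    return (
        len(codon) == 3
        and all(b in _BASE_INDEX for b in codon)
        and GENETIC_CODE[codon] != "*"
    )


def codon_site_counts(codon: str) -> CodonSiteCounts:
    """NG86 synonymous/nonsynonymous site counts for one sense codon.

    For each of the three positions, the synonymous fraction is the share of
    the three possible single-base changes that preserve the amino acid;
    changes to stop codons count as nonsynonymous.
    """
    codon = codon.upper()
    if not _is_sense(codon):
        raise UndefinedCodonError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                syn += 1.0 / 3.0
    return CodonSiteCounts(syn_sites=syn, nonsyn_sites=3.0 - syn)


def pathway_differences(codon_a: str, codon_b: str) -> PairwiseDifferences:
    """Classify the differences between two sense codons, averaging over all
    orderings of single-base steps; stop-containing pathways are discarded
    (all pathways used if every ordering passes through a stop)."""
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if not _is_sense(codon_a) or not _is_sense(codon_b):
        raise UndefinedCodonError(f"not sense codons: {codon_a!r}, {codon_b!r}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return PairwiseDifferences(0.0, 0.0)

    pathways: list[tuple[float, float, bool]] = []  # (syn, nonsyn, stop_free)
    for order in permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0.0
        stop_free = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            if GENETIC_CODE[nxt] == "*":
                stop_free = False
            current = nxt
        pathways.append((syn, nonsyn, stop_free))

    admissible = [p for p in pathways if p[2]] or pathways
    syn = float(np.mean([p[0] for p in admissible]))
    nonsyn = float(np.mean([p[1] for p in admissible]))
    return PairwiseDifferences(syn_diffs=syn, nonsyn_diffs=nonsyn)


# ---------------------------------------------------------------------------
# precomputed lookup tables (codon index = 16*b0 + 4*b1 + b2, A C G T = 0..3)
# ---------------------------------------------------------------------------

def _codon_index(codon: str) -> int:
    return (
        16 * _BASE_INDEX[codon[0]]
        + 4 * _BASE_INDEX[codon[1]]
        + _BASE_INDEX[codon[2]]
    )


def _build_tables():
    all_codons = [a + b + c for a in BASES for b in BASES for c in BASES]
    sense = np.zeros(64, dtype=bool)
    s_sites = np.zeros(64)
    n_sites = np.zeros(64)
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for codon in all_codons:
        i = _codon_index(codon)
        if GENETIC_CODE[codon] == "*":
            continue
        sense[i] = True
        counts = codon_site_counts(codon)
        s_sites[i] = counts.syn_sites
        n_sites[i] = counts.nonsyn_sites
    for ca in all_codons:
        if GENETIC_CODE[ca] == "*":
            continue
        for cb in all_codons:
            if GENETIC_CODE[cb] == "*":
                continue
            diffs = pathway_differences(ca, cb)
            sd[_codon_index(ca), _codon_index(cb)] = diffs.syn_diffs
            nd[_codon_index(ca), _codon_index(cb)] = diffs.nonsyn_diffs
    return sense, s_sites, n_sites, sd, nd


_SENSE, _S_SITES, _N_SITES, _SD, _ND = _build_tables()


def encode_codons(seq: str) -> np.ndarray:
    """Encode a nucleotide string as codon indices; -1 marks codons that are
    unusable (gap/N/ambiguity or stop)."""
    n_codons = len(seq) // 3
    out = np.full(n_codons, -1, dtype=np.int64)
    for k in range(n_codons):
        codon = seq[3 * k : 3 * k + 3]
        if all(b in _BASE_INDEX for b in codon):
            idx = _codon_index(codon)
            if _SENSE[idx]:
                out[k] = idx
    return out


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------

def pairwise_pn_ps(seq_a: str, seq_b: str) -> tuple[float, float, float, float]:
    """NG86 proportions for one aligned pair.

    Returns ``(pN, pS, N, S)`` where N and S are the means of the two
    sequences' summed nonsynonymous/synonymous site counts over the codon
    sites usable in both (gap/N/stop codons excluded pairwise).
    """
    if len(seq_a) != len(seq_b):
        raise NoDataError("sequences differ in length")
    if len(seq_a) % 3 != 0:
        raise NoDataError("sequence length is not a multiple of 3")
    a = encode_codons(seq_a)
    b = encode_codons(seq_b)
    usable = (a >= 0) & (b >= 0)
    if not usable.any():
        raise NoDataError("no usable codon sites in pair")
    au, bu = a[usable], b[usable]
    sd = _SD[au, bu].sum()
    nd = _ND[au, bu].sum()
    s_sites = 0.5 * (_S_SITES[au].sum() + _S_SITES[bu].sum())
    n_sites = 0.5 * (_N_SITES[au].sum() + _N_SITES[bu].sum())
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    return pn, ps, n_sites, s_sites


def jukes_cantor_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4)·ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4: JC distance undefined")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


_TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter nucleotide distance with pairwise deletion.

    d = -(1/2)·ln((1 - 2P - Q)·sqrt(1 - 2Q)) with P, Q the transition and
    transversion proportions over sites valid in both sequences.
    """
    if len(seq_a) != len(seq_b):
        raise NoDataError("sequences differ in length")
    comparable = transitions = transversions = 0
    for x, y in zip(seq_a, seq_b):
        if x not in _BASE_INDEX or y not in _BASE_INDEX:
            continue
        comparable += 1
        if x == y:
            continue
        if (x, y) in _TRANSITION_PAIRS:
            transitions += 1
        else:
            transversions += 1
    if comparable == 0:
        raise NoDataError("no comparable nucleotide sites")
    p = transitions / comparable
    q = transversions / comparable
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P log-domain violation (P={p:.3f}, Q={q:.3f})")
    return -0.5 * np.log(w1 * np.sqrt(w2))


def pairwise_dn_ds(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Jukes–Cantor-corrected dN and dS for one aligned pair."""
    pn, ps, _, _ = pairwise_pn_ps(seq_a, seq_b)
    return jukes_cantor_correct(pn), jukes_cantor_correct(ps)


# ---------------------------------------------------------------------------
# vectorized panel machinery
# ---------------------------------------------------------------------------

class _CodonPanel:
    """Per-pair, per-codon-site difference and site-count arrays for a panel,
    supporting fast recomputation under codon-column resampling."""

    def __init__(self, alleles: AlleleSet):
        if alleles.n < 2:
            raise NoDataError("need >= 2 sequences")
        codes = np.stack([encode_codons(s) for s in alleles.sequences])
        n, self.n_codons = codes.shape
        if self.n_codons == 0:
            raise NoDataError("zero-length alignment")
        iu, ju = np.triu_indices(n, k=1)
        a, b = codes[iu], codes[ju]  # (P, L)
        usable = (a >= 0) & (b >= 0)
        a_safe = np.where(usable, a, 0)
        b_safe = np.where(usable, b, 0)
        self.sd = np.where(usable, _SD[a_safe, b_safe], 0.0)
        self.nd = np.where(usable, _ND[a_safe, b_safe], 0.0)
        self.s_sites = np.where(
            usable, 0.5 * (_S_SITES[a_safe] + _S_SITES[b_safe]), 0.0
        )
        self.n_sites = np.where(
            usable, 0.5 * (_N_SITES[a_safe] + _N_SITES[b_safe]), 0.0
        )

    def _mean(self, num: np.ndarray, den: np.ndarray, strict: bool) -> np.ndarray:
        """JC-corrected per-pair distances -> mean over pairs, per column of
        the (pairs, replicates) inputs; saturated/no-data pairs become NaN.
        With ``strict`` an all-NaN column raises; otherwise it yields NaN
        (bootstrap replicates are simply dropped)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            p = num / den
            p = np.where(den > 0, p, np.nan)
            p = np.where(p < 0.75, p, np.nan)
            d = -0.75 * np.log1p(-4.0 * p / 3.0)
        excluded = int(np.isnan(d).sum())
        if excluded:
            logger.info("excluded %d saturated/no-data pair evaluations", excluded)
        empty = np.isnan(d).all(axis=0)
        if strict and empty.any():
            raise NoDataError("all pairs excluded (saturation or no data)")
        out = np.full(d.shape[1], np.nan)
        if (~empty).any():
            out[~empty] = np.nanmean(d[:, ~empty], axis=0)
        return out

    def point(self, statistic: str) -> float:
        col = np.ones((self.n_codons, 1))
        num = (self.nd if statistic == "dN" else self.sd) @ col
        den = (self.n_sites if statistic == "dN" else self.s_sites) @ col
        return float(self._mean(num, den, strict=True)[0])

    def bootstrap(self, statistic: str, counts: np.ndarray) -> np.ndarray:
        """Distances for resampled column-count matrices ``counts`` (L, R)."""
        num = (self.nd if statistic == "dN" else self.sd) @ counts
        den = (self.n_sites if statistic == "dN" else self.s_sites) @ counts
        return self._mean(num, den, strict=False)


class _NucPanel:
    """Per-pair, per-nucleotide-column transition/transversion indicators for
    the K2P statistic under nucleotide-column resampling."""

    def __init__(self, alleles: AlleleSet):
        if alleles.n < 2:
            raise NoDataError("need >= 2 sequences")
        mat = np.array(
            [[_BASE_INDEX.get(ch, -1) for ch in s] for s in alleles.sequences]
        )
        n, self.n_cols = mat.shape
        if self.n_cols == 0:
            raise NoDataError("zero-length alignment")
        iu, ju = np.triu_indices(n, k=1)
        a, b = mat[iu], mat[ju]
        valid = (a >= 0) & (b >= 0)
        diff = valid & (a != b)
        # A, G are purines (codes 0, 2): same parity <=> transition
        transition = diff & ((a % 2) == (b % 2))
        self.valid = valid.astype(float)
        self.ts = transition.astype(float)
        self.tv = (diff & ~transition).astype(float)

    def _mean(
        self, ts: np.ndarray, tv: np.ndarray, nc: np.ndarray, strict: bool
    ) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(nc > 0, ts / nc, np.nan)
            q = np.where(nc > 0, tv / nc, np.nan)
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            ok = (w1 > 0) & (w2 > 0)
            d = np.where(ok, -0.5 * np.log(np.where(ok, w1 * np.sqrt(np.abs(w2)), 1.0)), np.nan)
        empty = np.isnan(d).all(axis=0)
        if strict and empty.any():
            raise NoDataError("all pairs excluded (saturation or no data)")
        out = np.full(d.shape[1], np.nan)
        if (~empty).any():
            out[~empty] = np.nanmean(d[:, ~empty], axis=0)
        return out

    def point(self) -> float:
        col = np.ones((self.n_cols, 1))
        return float(
            self._mean(self.ts @ col, self.tv @ col, self.valid @ col, strict=True)[0]
        )

    def bootstrap(self, counts: np.ndarray) -> np.ndarray:
        return self._mean(
            self.ts @ counts, self.tv @ counts, self.valid @ counts, strict=False
        )


def mean_pairwise(alleles: AlleleSet, statistic: str) -> float:
    """Arithmetic mean of a pairwise statistic over all unordered pairs.

    ``statistic`` is one of ``dN``, ``dS``, ``d_k2p``.  Pairs hitting
    saturation or having no usable sites are excluded with a logged count.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}, got {statistic!r}")
    if statistic == "d_k2p":
        return _NucPanel(alleles).point()
    return _CodonPanel(alleles).point(statistic)


def _resample_counts(
    n_cols: int, replicates: int, seed: int
) -> np.ndarray:
    """Column-multiplicity matrix (n_cols, replicates); replicate streams are
    spawned from the seed by replicate index, so results are reproducible and
    order-independent."""
    children = np.random.SeedSequence(seed).spawn(replicates)
    counts = np.empty((n_cols, replicates))
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        cols = rng.integers(0, n_cols, size=n_cols)
        counts[:, r] = np.bincount(cols, minlength=n_cols)
    return counts


def bootstrap_se(
    alleles: AlleleSet, statistic: str, replicates: int = 1000, seed: int = 0
) -> SubstitutionEstimate:
    """Point estimate of ``mean_pairwise`` with a bootstrap standard error.

    The resampling unit is the codon column for dN/dS and the nucleotide
    column for the K2P distance; the SE is the standard deviation (ddof=1)
    of the replicate means.  Deterministic for a fixed seed.
    """
    if replicates < 2:
        raise ValueError(f"replicates must be >= 2, got {replicates}")
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}, got {statistic!r}")
    if statistic == "d_k2p":
        panel = _NucPanel(alleles)
        estimate = panel.point()
        counts = _resample_counts(panel.n_cols, replicates, seed)
        reps = panel.bootstrap(counts)
    else:
        panel = _CodonPanel(alleles)
        estimate = panel.point(statistic)
        counts = _resample_counts(panel.n_codons, replicates, seed)
        reps = panel.bootstrap(statistic, counts)
    n_bad = int(np.isnan(reps).sum())
    if n_bad:
        logger.info("%d bootstrap replicates dropped (no data)", n_bad)
    se = float(np.nanstd(reps, ddof=1))
    return SubstitutionEstimate(
        estimate=float(estimate), std_error=se, replicates=replicates, seed=seed
    )


def z_test_selection(
    dn: SubstitutionEstimate, ds: SubstitutionEstimate
) -> SelectionTest:
    """One-tailed Z-test of positive selection (alternative dN > dS).

    Z = (dN - dS)/sqrt(SE(dN)^2 + SE(dS)^2); the bootstrap variances are
    treated as independent.  When both SEs are zero and the estimates equal
    (e.g. a monomorphic panel) the test is the null point Z=0, p=0.5.
    """
    var = dn.std_error**2 + ds.std_error**2
    diff = dn.estimate - ds.estimate
    if var == 0.0:
        if diff == 0.0:
            z = 0.0
        else:
            raise DegenerateVarianceError(
                "zero bootstrap variance with unequal dN, dS"
            )
    else:
        z = diff / np.sqrt(var)
    p = float(norm.sf(z))
    ratio = dn.estimate / ds.estimate if ds.estimate > 0 else None
    return SelectionTest(dn=dn, ds=ds, ratio=ratio, z_stat=float(z), p_value=p)
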