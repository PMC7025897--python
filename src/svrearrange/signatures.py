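"""Structural-variant categories, count matrices, and signature extraction.

Each patient's classified clusters are divided into mutually exclusive
categories — the most frequent simple classes (deletions and tandem
duplications) split by size, replication timing and fragile-site occurrence,
plus categories for the other event classes (templated-insertion topologies
split by total template span, reciprocal events split by size, and so on).
Signatures are recurring probability profiles over these categories,
extracted from the patients x categories count matrix by KL-divergence
(Poisson) non-negative matrix factorization with stability-based rank
selection; a hierarchical Dirichlet process sampler is available as an
optional second backend (see :mod:`svrearrange.hdp`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .classification import Classification

log = logging.getLogger(__name__)

SIZE_SMALL_BP = 50_000       # small (<50-kb) deletions / TDs
SIZE_LARGE_BP = 500_000      # large (>500-kb) deletions / TDs and inversions
TI_SPAN_SPLIT_BP = 100_000   # templated-insertion total template span split
DEFAULT_MIN_COHORT_COUNT = 50


@dataclass(frozen=True)
class Category:
    """One mutually exclusive SV category (a predicate over classifications)."""

    name: str
    event_classes: tuple[str, ...]
    size_lo: Optional[int] = None      # [size_lo, size_hi) on the relevant span
    size_hi: Optional[int] = None
    rt: Optional[str] = None           # "early" / "late"
    fragile: Optional[bool] = None     # fragile-site categories
    translocation_adjacent: Optional[bool] = None

    def matches(self, event_class, size_bp, rt_label, fragile_flag, trans_adjacent) -> bool:
        if event_class not in self.event_classes:
            return False
        if self.fragile is not None and fragile_flag != self.fragile:
            return False
        if self.size_lo is not None and (size_bp is None or size_bp < self.size_lo):
            return False
        if self.size_hi is not None and (size_bp is None or size_bp >= self.size_hi):
            return False
        if self.rt is not None and rt_label != self.rt:
            return False
        if self.translocation_adjacent is not None and trans_adjacent != self.translocation_adjacent:
            return False
        return True


@dataclass
class CategoryCatalogue:
    """Ordered, versioned list of mutually exclusive categories."""

    version: str
    categories: list[Category]
    min_cohort_count: int = DEFAULT_MIN_COHORT_COUNT

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.categories]

    def assign(self, event_class, size_bp, rt_label, fragile_flag, trans_adjacent=False) -> str:
        for cat in self.categories:
            if cat.matches(event_class, size_bp, rt_label, fragile_flag, trans_adjacent):
                return cat.name
        return "complex_unclassified"


def default_catalogue(min_cohort_count: int = DEFAULT_MIN_COHORT_COUNT) -> CategoryCatalogue:
    """The default category set (version d1).

    Deletions and tandem duplications at fragile sites share one category;
    off-fragile ones are split at 50 kb / 500 kb, with the two smaller bins
    further split by replication timing (11 del/TD categories in total).
    Templated-insertion topologies are split at 100 kb of total template
    span; reciprocal inversions at 500 kb.
    """
    cats: list[Category] = [
        Category("fragile_site", ("deletion", "tandem_duplication"), fragile=True),
    ]
    for ec, tag in (("deletion", "del"), ("tandem_duplication", "td")):
        for size_lo, size_hi, stag in (
            (None, SIZE_SMALL_BP, "<50kb"),
            (SIZE_SMALL_BP, SIZE_LARGE_BP, "50-500kb"),
        ):
            for rt in ("early", "late"):
                cats.append(
                    Category(f"{tag}_{stag}_{rt}", (ec,), size_lo, size_hi, rt, fragile=False)
                )
        cats.append(Category(f"{tag}_>500kb", (ec,), SIZE_LARGE_BP, None, fragile=False))
    cats += [
        Category("recip_inv_small", ("reciprocal_inversion",), None, SIZE_LARGE_BP),
        Category("recip_inv_large", ("reciprocal_inversion",), SIZE_LARGE_BP, None),
        Category("unbal_translocation", ("unbalanced_translocation",)),
        Category("recip_translocation", ("reciprocal_translocation",)),
        Category("foldback_trans_adjacent", ("foldback_inversion",), translocation_adjacent=True),
        Category("foldback", ("foldback_inversion",)),
    ]
    for topo in ("cycle", "bridge", "chain"):
        ec = f"templated_insertion_{topo}"
        cats.append(Category(f"{topo}_<=100kb", (ec,), None, TI_SPAN_SPLIT_BP + 1))
        cats.append(Category(f"{topo}_>100kb", (ec,), TI_SPAN_SPLIT_BP + 1, None))
    cats += [
        Category("local_2jump_dup_trp_dup", ("local_2jump_dup_trp_dup",)),
        Category("local_2jump_inverted_dups", ("local_2jump_inverted_dups",)),
        Category("local_2jump_del_invdup", ("local_2jump_del_invdup",)),
        Category("local_n_jump", ("local_n_jump",)),
        Category("local_distant", ("local_distant",)),
        Category("chromoplexy", ("chromoplexy",)),
        Category("chromothripsis_like", ("chromothripsis_like",)),
        Category("complex_unclassified", ("complex_unclassified",)),
    ]
    return CategoryCatalogue("d1", cats, min_cohort_count)


# ---------------------------------------------------------------------------
# Replication-timing / fragile-site annotation helpers


def rt_labeler(track, grid) -> Callable[[str, int], str]:
    """Label positions early/late by replication-timing terciles.

    The track is oriented with higher values = earlier replication; ``early``
    is the top tercile, everything else (including the middle tercile) is
    grouped with ``late``.
    """
    vals = track.values[track.covered]
    hi = np.quantile(vals, 2 / 3) if len(vals) else np.inf

    def label(chrom: str, pos: int) -> str:
        v = track.values[grid.pixel_index(chrom, pos)]
        if np.isnan(v):
            return "late"
        return "early" if v >= hi else "late"

    return label


def fragile_site_checker(sites: Sequence[tuple[str, int, int]]) -> Callable[[str, int], bool]:
    def check(chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in sites)

    check.sites = list(sites)
    return check


def categorize(
    classification: Classification,
    catalogue: CategoryCatalogue,
    rt_label: Callable[[str, int], str],
    is_fragile: Callable[[str, int], bool],
    trans_adjacent: bool = False,
) -> str:
    """Map one classified cluster to its catalogue category."""
    ec = classification.event_class
    size = classification.details.get("size_bp")
    if ec.startswith("templated_insertion"):
        size = classification.details.get("template_span_bp")
    bk = classification.cluster.junctions[0].a if classification.cluster else None
    rt = rt_label(bk.chrom, bk.pos) if bk is not None else "late"
    fragile = False
    if classification.cluster is not None:
        fragile = any(
            is_fragile(b.chrom, b.pos)
            for j in classification.cluster.junctions
            for b in j.breakends
        )
    return catalogue.assign(ec, size, rt, fragile, trans_adjacent)


def build_category_counts(
    classifications_by_patient: dict[str, Sequence[Classification]],
    catalogue: CategoryCatalogue,
    rt_label: Callable[[str, int], str],
    is_fragile: Callable[[str, int], bool],
    apply_frequency_filter: bool = False,
) -> pd.DataFrame:
    """Patients x categories count matrix; each cluster increments one cell.

    With *apply_frequency_filter*, categories with cohort totals below the
    catalogue's minimum are folded into ``other_rare``.
    """
    names = catalogue.names
    counts = pd.DataFrame(
        0, index=sorted(classifications_by_patient), columns=names, dtype=int
    )
    for patient, classifications in classifications_by_patient.items():
        trans_pos = [
            bk
            for c in classifications
            if c.cluster is not None
            for j in c.cluster.junctions
            if j.orientation_class == "interchromosomal"
            for bk in j.breakends
        ]

        def near_translocation(c: Classification) -> bool:
            if c.event_class != "foldback_inversion" or c.cluster is None:
                return False
            return any(
                bk.chrom == t.chrom and abs(bk.pos - t.pos) < 1_000_000
                for j in c.cluster.junctions
                for bk in j.breakends
                for t in trans_pos
            )

        for c in classifications:
            cat = categorize(c, catalogue, rt_label, is_fragile, near_translocation(c))
            counts.loc[patient, cat] += 1
    if apply_frequency_filter:
        totals = counts.sum(axis=0)
        rare = [c for c in counts.columns if totals[c] < catalogue.min_cohort_count]
        if rare:
            counts["other_rare"] = counts[rare].sum(axis=1)
            counts = counts.drop(columns=rare)
    return counts


# ---------------------------------------------------------------------------
# NMF signature extraction


@dataclass
class SignatureSet:
    """Signature spectra (rows sum to one) and per-patient exposures."""

    signatures: pd.DataFrame  # K x categories
    exposures: pd.DataFrame   # patients x K

    def __post_init__(self):
        rs = self.signatures.sum(axis=1)
        nz = rs > 0
        self.signatures.loc[nz] = self.signatures.loc[nz].div(rs[nz], axis=0)


def _cosine_match(A: np.ndarray, B: np.ndarray) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Hungarian matching of signature rows by cosine similarity."""
    na = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-12)
    nb = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-12)
    sim = na @ nb.T
    k = min(A.shape[0], B.shape[0])
    rows, cols = linear_sum_assignment(-sim)
    pairs = list(zip(rows[:k], cols[:k]))
    return pairs, np.array([sim[r, c] for r, c in pairs])


def _nmf_fits(X, K, n_restarts, seed):
    import warnings as _warnings

    from sklearn.decomposition import NMF
    from sklearn.exceptions import ConvergenceWarning

    fits = []
    for r in range(n_restarts):
        model = NMF(
            n_components=K, beta_loss="kullback-leibler", solver="mu",
            init="random", random_state=seed + 7919 * r, max_iter=1000, tol=1e-5,
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(X)
        fits.append((model.reconstruction_err_, W, model.components_))
    return fits


def extract_signatures_nmf(
    counts: pd.DataFrame,
    k_range: Sequence[int] = range(2, 7),
    n_restarts: int = 30,
    seed: int = 0,
    stability_min: float = 0.95,
    min_rel_improvement: float = 0.05,
) -> tuple[SignatureSet, dict]:
    """KL-divergence NMF with seeded restarts and stability model selection.

    For each rank K the factorization is repeated from *n_restarts* random
    initializations; stability is the mean cosine of Hungarian-matched
    signatures between each restart and the best-loss solution.  The chosen K
    is the largest stable rank for which every step up from the smallest rank
    still improves reconstruction error by at least *min_rel_improvement*
    (an elbow rule); if no rank is stable the report flags it and the most
    stable rank is returned.
    """
    X = counts.to_numpy(dtype=float)
    keep = X.sum(axis=1) > 0
    if not keep.all():
        log.warning("dropping %d all-zero patients", (~keep).sum())
        X = X[keep]
    patients = counts.index[keep]
    k_range = [k for k in k_range if 2 <= k <= min(X.shape) - 1] or [2]

    report = {"ranks": {}, "warnings": []}
    solutions = {}
    for K in k_range:
        fits = _nmf_fits(X, K, n_restarts, seed)
        best = min(fits, key=lambda f: f[0])
        cosines = []
        for err, W, H in fits:
            _, cos = _cosine_match(H, best[2])
            cosines.append(cos.mean())
        stability = float(np.mean(cosines))
        report["ranks"][K] = {"stability": stability, "error": float(best[0])}
        solutions[K] = best

    ks = sorted(report["ranks"])
    errors = {K: report["ranks"][K]["error"] for K in ks}
    stable = [K for K in ks if report["ranks"][K]["stability"] >= stability_min]
    if not stable:
        report["warnings"].append("no stable solution at any rank")
        chosen = min(ks)
    else:
        chosen = stable[0]
        for prev, K in zip(ks, ks[1:]):
            if K not in stable:
                break
            rel = (errors[prev] - errors[K]) / max(errors[prev], 1e-12)
            if rel >= min_rel_improvement:
                chosen = K
            else:
                break
        if chosen == min(ks) and len(ks) > 1:
            report["warnings"].append(
                "smallest rank chosen; data may be effectively rank-deficient"
            )
    report["chosen_k"] = chosen

    err, W, H = solutions[chosen]
    row_sums = H.sum(axis=1)
    signatures = pd.DataFrame(
        H, index=[f"SV{k + 1}" for k in range(chosen)], columns=counts.columns
    )
    exposures = pd.DataFrame(
        W * row_sums[np.newaxis, :], index=patients, columns=signatures.index
    )
    return SignatureSet(signatures, exposures), report


def split_half_stability(
    counts: pd.DataFrame,
    extractor: Callable[[pd.DataFrame, int], tuple[SignatureSet, dict]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Extract signatures in two random halves of the cohort and report the
    cosine similarities of Hungarian-matched signature pairs."""
    if len(counts) < 20:
        raise ValueError("need >= 20 patients for a split-half check")
    if extractor is None:
        extractor = lambda c, s: extract_signatures_nmf(c, seed=s)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(counts))
    half = len(counts) // 2
    c1 = counts.iloc[perm[:half]]
    c2 = counts.iloc[perm[half:]]
    s1, _ = extractor(c1, seed + 1)
    s2, _ = extractor(c2, seed + 2)
    pairs, cos = _cosine_match(s1.signatures.to_numpy(), s2.signatures.to_numpy())
    return pd.DataFrame(
        {
            "signature_half1": [s1.signatures.index[i] for i, _ in pairs],
            "signature_half2": [s2.signatures.index[j] for _, j in pairs],
            "cosine": cos,
        }
    )


# ---------------------------------------------------------------------------
# Driver-gene association


@dataclass
class DriverAssociation:
    gene_group: str
    signature: str
    effect_size: float  # signature exposure added per mutated genome
    p: float
    q: Optional[float] = None
    n_mutated: int = 0


def associate_drivers(
    exposures: pd.DataFrame,
    gene_status: pd.DataFrame,
    histology: pd.Series,
    gene_groups: Optional[dict[str, list[str]]] = None,
    min_mutated: int = 3,
) -> list[DriverAssociation]:
    """Linear models of signature exposure on gene status, histology-adjusted.

    For every (gene group, signature) pair fits
    ``exposure ~ mutated + C(histology)`` by OLS, takes the two-sided test on
    the gene coefficient, and applies Benjamini-Hochberg across all pairs.
    Gene groups pool related genes (e.g. the mismatch-repair MSH family);
    groups mutated in fewer than *min_mutated* patients are skipped.
    """
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    if gene_groups is None:
        gene_groups = {g: [g] for g in gene_status.columns}
    patients = exposures.index
    hist_dummies = pd.get_dummies(histology.loc[patients], drop_first=True, dtype=float)

    results: list[DriverAssociation] = []
    for group, genes in sorted(gene_groups.items()):
        present = [g for g in genes if g in gene_status.columns]
        if not present:
            continue
        status = (gene_status.loc[patients, present].sum(axis=1) > 0).astype(float)
        n_mut = int(status.sum())
        if n_mut < min_mutated:
            log.info("gene group %s mutated in %d < %d patients; skipped", group, n_mut, min_mutated)
            continue
        X = pd.concat([status.rename("mutated"), hist_dummies], axis=1)
        X = sm.add_constant(X)
        for sig in exposures.columns:
            fit = sm.OLS(exposures[sig].astype(float), X).fit()
            results.append(
                DriverAssociation(
                    group, sig, float(fit.params["mutated"]),
                    float(fit.pvalues["mutated"]), n_mutated=n_mut,
                )
            )
    if results:
        _, qvals, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q = float(q)
    return results
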