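"""OTU-table computations: rarefaction, richness, expression ratios.

Amplicon (pyrotag) libraries from DNA (rRNA genes) and cDNA
(reverse-transcribed rRNA) are summarized as OTU count tables with
taxonomy strings.  Richness is estimated with the nonparametric Chao1
and ACE estimators over repeated rarefaction to a common depth;
activity is proxied by per-taxon cDNA:DNA relative-abundance ratios,
restricted to genera above a minimum DNA relative abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "OtuTable",
    "DiversityEstimate",
    "rarefy",
    "chao1",
    "ace",
    "richness_summary",
    "relative_abundance",
    "expression_ratio",
]

logger = logging.getLogger(__name__)

#: Taxonomy positions recognized by name (strings are ordered
#: phylum → genus, possibly truncated).
RANKS = ("phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class OtuTable:
    """Sample × OTU counts plus per-OTU taxonomy.

    ``counts`` has OTU ids as index and sample ids as columns;
    ``taxonomy`` maps OTU id → ordered taxonomy labels.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("OTU counts must be integers")
            object.__setattr__(self, "counts", self.counts.astype(np.int64))
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")
        missing = set(self.counts.index) - set(self.taxonomy)
        if missing:
            raise ValueError(f"OTUs without taxonomy: {sorted(missing)[:5]}")
        for otu, tax in self.taxonomy.items():
            if len(tax) < 1:
                raise ValueError(f"OTU {otu!r} has empty taxonomy")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def depths(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[sample_id].to_numpy()


def rarefy(counts: np.ndarray, depth: int,
           seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    Multivariate-hypergeometric draw, as in rarefying a sequence
    library to the smallest library size.
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds library size {total}")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return rng.multivariate_hypergeometric(counts, depth)


def _freqs(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    pos = counts[counts > 0]
    if pos.size == 0:
        raise ValueError("empty sample: no OTU has a positive count")
    return pos


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness estimate from singleton/doubleton frequencies.

    Classic form S_obs + F1²/(2·F2); when no doubletons exist the
    bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) is used instead.
    """
    pos = _freqs(counts)
    s_obs = pos.size
    f1 = int(np.sum(pos == 1))
    f2 = int(np.sum(pos == 2))
    if f2 > 0:
        return s_obs + f1**2 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ace(counts: np.ndarray, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    OTUs with ≤ ``rare_threshold`` reads form the rare group; sample
    coverage C_ACE = 1 − F1/N_rare, and

        ACE = S_abund + S_rare/C_ACE + (F1/C_ACE)·γ²,

    with γ² the coefficient of variation of the rare frequencies,
    clamped at 0.  If every rare individual is a singleton (C_ACE = 0)
    the estimate falls back to Chao1 with a warning.
    """
    pos = _freqs(counts)
    rare = pos[pos <= rare_threshold]
    s_abund = int(np.sum(pos > rare_threshold))
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int(np.sum(rare == 1))
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        logger.warning("all rare individuals are singletons; ACE undefined, "
                       "falling back to Chao1")
        return chao1(counts)
    ks = np.arange(1, rare_threshold + 1)
    fk = np.array([np.sum(rare == k) for k in ks])
    sum_k = float(np.sum(ks * (ks - 1) * fk))
    if n_rare > 1:
        gamma2 = max(0.0, s_rare * sum_k / (c_ace * n_rare * (n_rare - 1)) - 1.0)
    else:
        gamma2 = 0.0
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


@dataclass(frozen=True)
class DiversityEstimate:
    """Richness summary for one sample over rarefaction iterations."""

    sample_id: str
    depth: int
    observed_mean: float
    observed_sd: float
    chao1_mean: float
    chao1_sd: float
    ace_mean: float
    ace_sd: float
    n_iterations: int


def richness_summary(table: OtuTable, depth: int, n_iter: int = 100,
                     seed: int | None = None,
                     rare_threshold: int = 10) -> list[DiversityEstimate]:
    """Observed/Chao1/ACE mean and SD over repeated rarefactions.

    Each sample is independently rarefied ``n_iter`` times to
    ``depth`` and the estimators averaged, mirroring subsampling to
    the smallest library size.
    """
    if depth > int(table.depths().min()):
        raise ValueError(
            f"depth {depth} exceeds smallest library ({int(table.depths().min())})")
    rng = np.random.default_rng(seed)
    out = []
    for sample in table.sample_ids:
        counts = table.sample_counts(sample)
        obs = np.empty(n_iter)
        ch = np.empty(n_iter)
        ac = np.empty(n_iter)
        for i in range(n_iter):
            sub = rarefy(counts, depth, rng)
            obs[i] = np.sum(sub > 0)
            ch[i] = chao1(sub)
            ac[i] = ace(sub, rare_threshold=rare_threshold)
        sd = lambda x: float(np.std(x, ddof=1)) if n_iter > 1 else 0.0
        out.append(DiversityEstimate(
            sample_id=sample, depth=depth,
            observed_mean=float(obs.mean()), observed_sd=sd(obs),
            chao1_mean=float(ch.mean()), chao1_sd=sd(ch),
            ace_mean=float(ac.mean()), ace_sd=sd(ac),
            n_iterations=n_iter))
    return out


def _level_index(level: int | str) -> int:
    if isinstance(level, str):
        try:
            return RANKS.index(level)
        except ValueError:
            raise ValueError(f"unknown taxonomy level {level!r}; "
                             f"known: {RANKS}") from None
    return int(level)


def _taxon_at(tax: tuple[str, ...], idx: int) -> str:
    if idx < len(tax) and tax[idx]:
        return tax[idx]
    return "unclassified"


def relative_abundance(table: OtuTable, level: int | str) -> pd.DataFrame:
    """Per-sample proportions aggregated at a taxonomy level.

    ``level`` is a rank name (phylum … genus) or a 0-based position in
    the taxonomy string; OTUs whose taxonomy is truncated above that
    level pool into "unclassified".  Columns sum to 1 per sample.
    """
    idx = _level_index(level)
    depths = table.depths()
    if (depths == 0).any():
        empty = list(depths[depths == 0].index)
        raise ValueError(f"empty sample(s): {empty}")
    labels = [_taxon_at(table.taxonomy[otu], idx) for otu in table.counts.index]
    grouped = table.counts.groupby(pd.Index(labels, name="taxon")).sum()
    return grouped / depths


def expression_ratio(dna: OtuTable, cdna: OtuTable,
                     level: int | str = "genus",
                     min_dna_frac: float = 0.01
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon cDNA:DNA relative-abundance ratios.

    Only taxa whose DNA relative abundance exceeds ``min_dna_frac``
    (default 1 %) are examined; excluded taxa — including any present
    in the cDNA library only — are returned in the second frame with
    the reason.  Sample columns must pair one-to-one between tables.

    Returns
    -------
    (ratios, excluded)
        ``ratios`` columns: sample, taxon, dna_frac, cdna_frac, ratio.
        ``excluded`` columns: sample, taxon, dna_frac, reason.
    """
    if list(dna.sample_ids) != list(cdna.sample_ids):
        raise ValueError(
            f"sample columns do not pair: DNA {dna.sample_ids} vs "
            f"cDNA {cdna.sample_ids}")
    ra_dna = relative_abundance(dna, level)
    ra_cdna = relative_abundance(cdna, level)
    taxa = ra_dna.index.union(ra_cdna.index)
    ra_dna = ra_dna.reindex(taxa, fill_value=0.0)
    ra_cdna = ra_cdna.reindex(taxa, fill_value=0.0)
    rows, excluded = [], []
    for sample in dna.sample_ids:
        for taxon in taxa:
            d = float(ra_dna.loc[taxon, sample])
            c = float(ra_cdna.loc[taxon, sample])
            if d > min_dna_frac:
                rows.append({"sample": sample, "taxon": taxon,
                             "dna_frac": d, "cdna_frac": c, "ratio": c / d})
            else:
                reason = ("absent from DNA library" if d == 0
                          else f"DNA fraction {d:.4f} <= {min_dna_frac}")
                excluded.append({"sample": sample, "taxon": taxon,
                                 "dna_frac": d, "reason": reason})
    ratios = pd.DataFrame(rows, columns=["sample", "taxon", "dna_frac",
                                         "cdna_frac", "ratio"])
    excl = pd.DataFrame(excluded, columns=["sample", "taxon", "dna_frac",
                                           "reason"])
    return ratios, excl
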