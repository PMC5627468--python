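"""Linkage-disequilibrium redundancy pruning for unphased genotype panels.

Pairwise LD between markers is estimated as the squared product-moment
correlation of the two dosage columns over pairwise-complete samples — the
composite LD estimate, which needs no phasing and no haplotype EM.  A greedy
pass in panel order then keeps one marker per redundant set: a marker is
dropped iff its r-squared with an already-kept marker exceeds the threshold
(default 0.90), so the earlier-listed marker always represents the group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_panel import GenotypeMatrix

__all__ = ["NonEstimableLdError", "PruneResult", "genotype_r2", "prune_ld"]

logger = logging.getLogger(__name__)


class NonEstimableLdError(ValueError):
    """r-squared cannot be estimated (too few complete pairs or constant column)."""


@dataclass
class PruneResult:
    """Outcome of one pruning pass.

    ``excluded`` records, for each dropped marker, the already-kept
    representative it was redundant with and their r-squared.
    """

    kept: list[str]
    excluded: list[tuple[str, str, float]]
    threshold: float

    @property
    def excluded_rsids(self) -> list[str]:
        return [e[0] for e in self.excluded]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.excluded, columns=["excluded_rsid", "representative_rsid", "r2"]
        )

    def write(self, path) -> None:
        """Two-section report: kept list, then exclusions with their r²."""
        with open(path, "w") as fh:
            fh.write(f"# LD pruning at r2 > {self.threshold}\n")
            fh.write("## kept\nrsid\n")
            for r in self.kept:
                fh.write(f"{r}\n")
            fh.write("## excluded\nexcluded_rsid\trepresentative_rsid\tr2\n")
            for ex, rep, r2 in self.excluded:
                fh.write(f"{ex}\t{rep}\t{r2:.6f}\n")


def genotype_r2(g1: np.ndarray, g2: np.ndarray, min_n: int = 3) -> float:
    """Composite LD r² between two dosage columns.

    Squared Pearson correlation over samples non-missing in both columns.
    Allele-orientation flips (d -> 2 - d) leave the value unchanged.

    Raises :class:`NonEstimableLdError` with fewer than ``min_n`` pairwise
    complete samples or when either column is constant on the complete set.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage columns differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < min_n:
        raise NonEstimableLdError(
            f"only {a.size} pairwise-complete samples (need >= {min_n})"
        )
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        raise NonEstimableLdError("constant genotype column on the complete set")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def prune_ld(genotypes: GenotypeMatrix, threshold: float = 0.90) -> PruneResult:
    """Greedy LD pruning in panel order at ``r² > threshold``.

    Deterministic given input order: each marker is tested against the
    already-kept set and excluded at the first representative exceeding the
    threshold, so earlier-listed markers win ties and every representative is
    itself kept.  Non-estimable pairs are treated as below threshold with a
    warning.  Cross-chromosome pairs are checked too — r² above threshold
    across chromosomes would flag a data artifact worth surfacing.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    kept_idx: list[int] = []
    excluded: list[tuple[str, str, float]] = []
    for j, marker in enumerate(genotypes.markers):
        representative = None
        for k in kept_idx:
            try:
                r2 = genotype_r2(genotypes.dosages[:, k], genotypes.dosages[:, j])
            except NonEstimableLdError as err:
                warnings.warn(
                    f"r² non-estimable for {genotypes.markers[k].rsid} vs "
                    f"{marker.rsid} ({err}); treated as unlinked",
                    stacklevel=2,
                )
                continue
            if r2 > threshold:
                representative = (genotypes.markers[k].rsid, r2)
                break
        if representative is None:
            kept_idx.append(j)
        else:
            excluded.append((marker.rsid, representative[0], representative[1]))
    result = PruneResult(
        kept=[genotypes.markers[j].rsid for j in kept_idx],
        excluded=excluded,
        threshold=threshold,
    )
    logger.info(
        "LD pruning: %d markers in, %d kept, %d excluded at r2 > %s",
        len(genotypes.markers), len(result.kept), len(excluded), threshold,
    )
    return result
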