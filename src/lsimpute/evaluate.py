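"""Concordance evaluation of imputed genotypes against a gold standard.

Implements the standard post-imputation protocol: filter sites by the
maximum posterior genotype probability (GP), call the argmax genotype, and
report the fraction of evaluated sites that match the truth — over all
sites or restricted to truth-heterozygous sites (the harder and less
chance-inflated subset) — optionally stratified over equal-width minor
allele frequency bins computed from the reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConcordanceReport",
    "gp_filter",
    "imputed_genotypes",
    "concordance",
    "maf_assign_bins",
    "maf_bin_summary",
]


def gp_filter(gp: np.ndarray, threshold: float) -> np.ndarray:
    """Keep mask: sites whose maximum GP reaches the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return np.asarray(gp).max(axis=1) >= threshold


def imputed_genotypes(gp: np.ndarray) -> np.ndarray:
    """Argmax genotype per site; ties break toward the lower genotype code."""
    return np.argmax(np.asarray(gp), axis=1)


@dataclass
class ConcordanceReport:
    """Concordance summary for one imputed sample.

    ``comparable`` counts sites where truth overlaps the (unfiltered)
    output; ``evaluated`` additionally applies the GP filter mask.  When no
    site survives, ``concordance`` is NaN and ``defined`` is False.
    """

    threshold: float
    het_only: bool
    n_comparable: int
    n_evaluated: int
    n_matches: int
    concordance: float
    defined: bool
    evaluated_fraction: float
    bins: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "threshold": self.threshold,
            "het_only": self.het_only,
            "n_comparable": self.n_comparable,
            "n_evaluated": self.n_evaluated,
            "n_matches": self.n_matches,
            "concordance": self.concordance,
            "defined": self.defined,
            "evaluated_fraction": self.evaluated_fraction,
        }
        if self.bins is not None:
            d["bins"] = self.bins.to_dict(orient="records")
        return d

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for key, value in self.to_dict().items():
                if key == "bins":
                    continue
                fh.write(f"{key}\t{value}\n")
        if self.bins is not None:
            bin_path = str(path) + ".bins.tsv"
            self.bins.to_csv(bin_path, sep="\t", index=False)


def concordance(
    gp: np.ndarray,
    truth: np.ndarray,
    keep: np.ndarray | None = None,
    het_only: bool = False,
    threshold: float | None = None,
) -> ConcordanceReport:
    """Genotype concordance of argmax-GP calls against truth genotypes.

    ``truth`` uses -1 for missing; ``keep`` is a per-site mask (typically
    from :func:`gp_filter`); passing ``threshold`` builds the mask here and
    records it in the report.
    """
    gp = np.asarray(gp)
    truth = np.asarray(truth)
    if gp.shape[0] != truth.shape[0]:
        raise ValueError("imputed and truth must be aligned on identical sites")
    if threshold is not None:
        keep = gp_filter(gp, threshold)
    elif keep is None:
        keep = np.ones(truth.shape[0], dtype=bool)
        threshold = 0.0
    else:
        threshold = float("nan")
    comparable = truth >= 0
    if het_only:
        comparable = comparable & (truth == 1)
    evaluated = comparable & keep
    calls = imputed_genotypes(gp)
    n_eval = int(evaluated.sum())
    n_match = int(np.sum(calls[evaluated] == truth[evaluated]))
    defined = n_eval > 0
    return ConcordanceReport(
        threshold=float(threshold),
        het_only=het_only,
        n_comparable=int(comparable.sum()),
        n_evaluated=n_eval,
        n_matches=n_match,
        concordance=n_match / n_eval if defined else float("nan"),
        defined=defined,
        evaluated_fraction=n_eval / comparable.sum() if comparable.sum() else float("nan"),
    )


def maf_assign_bins(maf: np.ndarray, n_bins: int = 25) -> np.ndarray:
    """Equal-width, right-closed bins on [0, 0.5]; 1-based bin indices.

    MAF exactly 0 falls in bin 1, MAF exactly 0.5 in the top bin.
    """
    width = 0.5 / n_bins
    idx = np.ceil(np.asarray(maf, dtype=float) / width).astype(int)
    return np.clip(idx, 1, n_bins)


def maf_bin_summary(
    gp: np.ndarray,
    truth: np.ndarray,
    panel_maf: np.ndarray,
    keep: np.ndarray | None = None,
    het_only: bool = False,
    n_bins: int = 25,
) -> pd.DataFrame:
    """Per-MAF-bin concordance and evaluated counts.

    MAF comes from the reference panel (min(f, 1-f) of the panel alt
    frequency).  Bin counts partition the evaluated sites.
    """
    gp = np.asarray(gp)
    truth = np.asarray(truth)
    panel_maf = np.asarray(panel_maf, dtype=float)
    if keep is None:
        keep = np.ones(truth.shape[0], dtype=bool)
    comparable = truth >= 0
    if het_only:
        comparable = comparable & (truth == 1)
    evaluated = comparable & keep
    calls = imputed_genotypes(gp)
    match = evaluated & (calls == np.where(truth >= 0, truth, -9))
    bins = maf_assign_bins(panel_maf, n_bins)
    width = 0.5 / n_bins
    rows = []
    for b in range(1, n_bins + 1):
        sel = evaluated & (bins == b)
        n_eval = int(sel.sum())
        n_match = int(match[sel].sum())
        rows.append(
            {
                "bin": b,
                "maf_low": (b - 1) * width,
                "maf_high": b * width,
                "n_evaluated": n_eval,
                "n_matches": n_match,
                "concordance": n_match / n_eval if n_eval else float("nan"),
            }
        )
    return pd.DataFrame(rows)
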