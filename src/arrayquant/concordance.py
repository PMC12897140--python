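"""Cross-platform concordance: protein-array vs transcript fold-changes.

Protein analytes are matched to transcript gene symbols through a mapping
table (one covering the packaged 105-analyte panel ships with the
package, e.g. ENA-78 -> CXCL5, MCP-3 -> CCL7, DPPIV -> DPP4).  For each
matched pair, each platform casts a directional call: *up* if significant
with positive log2FC, *down* if significant with negative log2FC, else
*neutral*.  Protein significance is the joint |log2FC| > 1 & Z > 0.5
gate; transcript significance is adjusted p < 0.01 & |log2FC| > 1.

Agreement is summarized in a 2x2 contingency table — N_overlap
(concordant direction on both platforms), N_cyt / N_rna (directional on
one platform only), N_neither — tested with a one-sided Fisher's exact
test (alternative "greater"; p < 0.05 called significant), plus the
Pearson correlation of the paired log2FCs.

Pairs that are directional on both platforms but in *opposite* directions
are not overlap; by default each such pair credits both N_cyt and N_rna
("split" mode), with a "neither" mode available that sends them to
N_neither instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, StatsError

RNA_PADJ_GATE = 0.01
RNA_FC_GATE = 1.0
FISHER_ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable:
    n_overlap: int
    n_cyt: int
    n_rna: int
    n_neither: int

    @property
    def total(self) -> int:
        return self.n_overlap + self.n_cyt + self.n_rna + self.n_neither

    def as_array(self) -> np.ndarray:
        return np.array([[self.n_overlap, self.n_cyt], [self.n_rna, self.n_neither]])


def load_symbol_map() -> pd.DataFrame:
    """Packaged analyte -> HGNC gene symbol mapping for the 105-analyte panel."""
    with resources.files("arrayquant.data").joinpath("human_xl_symbols.csv").open() as fh:
        return pd.read_csv(fh)


def match_symbols(
    cyt: pd.DataFrame,
    rna: pd.DataFrame,
    mapping: pd.DataFrame | None = None,
    comparison: str = "",
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Inner-join protein analytes with transcripts on gene symbol.

    ``cyt`` needs columns analyte, log2FC, significant; ``rna`` needs
    symbol, log2FC, padj.  Symbol matching is case-insensitive.  Returns
    the matched pair table and a report of unmatched entities per side.
    """
    mapping = mapping if mapping is not None else load_symbol_map()
    if mapping["analyte"].duplicated().any() or mapping["symbol"].str.upper().duplicated().any():
        raise ConfigError("duplicate entries in analyte/symbol mapping")
    m = mapping.assign(_sym=mapping["symbol"].str.upper())
    c = cyt.merge(m[["analyte", "_sym", "symbol"]], on="analyte", how="inner")
    r = rna.assign(_sym=rna["symbol"].str.upper()).drop(columns=["symbol"])
    pairs = c.merge(r, on="_sym", suffixes=("_cyt", "_rna"), how="inner")
    pairs = pairs.rename(
        columns={
            "log2FC_cyt": "cyt_log2FC",
            "log2FC_rna": "rna_log2FC",
            "significant": "cyt_significant",
        }
    )
    pairs["rna_significant"] = (pairs["padj"] < RNA_PADJ_GATE) & (
        pairs["rna_log2FC"].abs() > RNA_FC_GATE
    )
    pairs["comparison"] = comparison
    unmatched = {
        "cytokine": sorted(set(cyt["analyte"]) - set(pairs["analyte"])),
        "rna": sorted(set(rna["symbol"].str.upper()) - set(pairs["_sym"])),
    }
    cols = [
        "analyte",
        "symbol",
        "comparison",
        "cyt_log2FC",
        "rna_log2FC",
        "cyt_significant",
        "rna_significant",
    ]
    return pairs[cols], unmatched


def _direction(fc: pd.Series, significant: pd.Series) -> pd.Series:
    d = pd.Series("neutral", index=fc.index)
    d[significant & (fc > 0)] = "up"
    d[significant & (fc < 0)] = "down"
    return d


def build_contingency(
    pairs: pd.DataFrame, n_total: int | None = None, discordant: str = "split"
) -> ContingencyTable:
    """Directional 2x2 table from a matched pair list.

    ``n_total`` defaults to the number of pairs.  ``discordant`` controls
    opposite-direction pairs: "split" credits N_cyt and N_rna each;
    "neither" counts them in N_neither.
    """
    if discordant not in ("split", "neither"):
        raise ConfigError("discordant must be 'split' or 'neither'")
    cyt = _direction(pairs["cyt_log2FC"], pairs["cyt_significant"])
    rna = _direction(pairs["rna_log2FC"], pairs["rna_significant"])
    both_dir = (cyt != "neutral") & (rna != "neutral")
    overlap = int((both_dir & (cyt == rna)).sum())
    disc = int((both_dir & (cyt != rna)).sum())
    cyt_only = int(((cyt != "neutral") & (rna == "neutral")).sum())
    rna_only = int(((rna != "neutral") & (cyt == "neutral")).sum())
    if discordant == "split":
        cyt_only += disc
        rna_only += disc
    n = n_total if n_total is not None else len(pairs)
    n_neither = n - (overlap + cyt_only + rna_only)
    if n_neither < 0:
        raise StatsError(
            f"total N={n} smaller than directional counts "
            f"({overlap}+{cyt_only}+{rna_only})"
        )
    return ContingencyTable(overlap, cyt_only, rna_only, n_neither)


def fisher_exact_greater(table: ContingencyTable) -> float:
    """One-sided Fisher's exact test: P(X >= N_overlap) under fixed margins."""
    _, p = stats.fisher_exact(table.as_array(), alternative="greater")
    return float(p)


def platform_correlation(pairs: pd.DataFrame, subset: str = "all") -> float:
    """Pearson correlation of (protein log2FC, transcript log2FC).

    ``subset="significant_only"`` restricts to transcript-significant
    pairs (the RNA gate); needs >= 3 pairs and non-degenerate variance.
    """
    if subset == "significant_only":
        pairs = pairs[pairs["rna_significant"]]
    elif subset != "all":
        raise ConfigError("subset must be 'all' or 'significant_only'")
    if len(pairs) < 3:
        raise StatsError(f"need >= 3 pairs for a correlation, got {len(pairs)}")
    x = pairs["cyt_log2FC"].to_numpy(dtype=float)
    y = pairs["rna_log2FC"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance on one platform; correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def pool_comparisons(pair_lists: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool matched pairs across treatment/genotype comparisons.

    Pooling is plain concatenation: each (analyte, comparison) pair is one
    observation in the pooled contingency and correlation analyses.
    """
    if not pair_lists:
        raise StatsError("nothing to pool")
    return pd.concat(pair_lists, ignore_index=True)
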