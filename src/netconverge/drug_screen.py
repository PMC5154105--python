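"""Drug-signature reversal screen.

Each drug signature is a differential-expression table (treatment vs vehicle)
reduced to up- and down-regulated gene sets at an FDR cutoff; signatures with
fewer than a minimum number of significant genes are ineligible. The screen
asks which drugs up-regulate a disease-downregulated module: a one-tailed
(greater) Fisher test of the module against each drug's up-set within the
expressed background, BH-corrected across all tested signatures. A direction
test reports the fractions of module genes a treatment moves up and down,
with one-tailed Fisher tests for each direction, for replication in an
independent treatment dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_enrichment import EnrichmentResult, bh_adjust, fisher_test_2x2


@dataclass
class DrugSignature:
    drug: str
    cell_line: str
    concentration: float
    up_set: set[str]
    down_set: set[str]
    eligible: bool


@dataclass
class DrugSignatureLibrary:
    signatures: list[DrugSignature] = field(default_factory=list)

    def eligible(self) -> list[DrugSignature]:
        return [s for s in self.signatures if s.eligible]


def drug_de_sets(
    de_table: pd.DataFrame,
    drug: str,
    cell_line: str = "",
    concentration: float = float("nan"),
    fdr_cut: float = 0.10,
    min_de_genes: int = 10,
) -> DrugSignature:
    """Reduce a drug's DE table to significant up/down gene sets.

    up_set = {padj < fdr_cut, log2fc > 0}; down_set analogous with
    log2fc < 0 (genes with zero fold change join neither); the signature is
    eligible when the sets together hold at least ``min_de_genes`` genes.
    """
    required = {"gene", "log2fc", "padj"}
    if not required <= set(de_table.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    sig = de_table[de_table["padj"].astype(float) < fdr_cut]
    up = set(sig.loc[sig["log2fc"].astype(float) > 0, "gene"])
    down = set(sig.loc[sig["log2fc"].astype(float) < 0, "gene"])
    return DrugSignature(
        drug=drug,
        cell_line=cell_line,
        concentration=concentration,
        up_set=up,
        down_set=down,
        eligible=len(up) + len(down) >= min_de_genes,
    )


def _directional_fet(
    module: set[str], gene_set: set[str], background: set[str], alternative: str
) -> EnrichmentResult:
    mod = module & background
    tgt = gene_set & background
    overlap = len(mod & tgt)
    table = [
        [overlap, len(mod) - overlap],
        [len(tgt) - overlap, len(background) - len(mod) - len(tgt) + overlap],
    ]
    res = fisher_test_2x2(table, alternative=alternative)
    res.extra["overlap"] = overlap
    return res


def screen_drugs(
    library: DrugSignatureLibrary,
    module: set[str],
    background: set[str],
    direction: str = "up",
) -> pd.DataFrame:
    """Rank drug signatures by one-tailed overlap of the module with their up-sets.

    The default tests up-sets (reversal of a downregulated disease module);
    ``direction="down"`` tests down-sets instead, for an upregulated disease
    module. P values are BH-adjusted across every eligible signature and
    results sorted by adjusted P, raw P, then drug ID. The overlap with the
    opposite-direction set is reported as a secondary column.
    """
    if not module & background:
        raise ValueError("module does not intersect the background")
    entries = library.eligible()
    if not entries:
        raise ValueError("no eligible drug signatures")
    rows = []
    for sig in entries:
        primary = sig.up_set if direction == "up" else sig.down_set
        secondary = sig.down_set if direction == "up" else sig.up_set
        res = _directional_fet(module, primary, background, alternative="greater")
        rows.append(
            {
                "drug": sig.drug,
                "cell_line": sig.cell_line,
                "concentration": sig.concentration,
                "overlap": res.extra["overlap"],
                "set_size": len(primary & background),
                "odds_ratio": res.statistic,
                "p_value": res.p_value,
                "secondary_overlap": len(module & secondary & background),
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_adjust(out["p_value"].values)
    out = out.sort_values(
        ["adjusted_p", "p_value", "drug"], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def replication_direction_test(
    de_table: pd.DataFrame,
    module: set[str],
    background: set[str],
    fdr_cut: float = 0.10,
) -> tuple[float, float, EnrichmentResult, EnrichmentResult]:
    """Fractions of mapped module genes a treatment up- and down-regulates.

    up_fraction = |module ∩ up_set| / |module ∩ DE-table universe| (down
    analogous); the up overlap is Fisher-tested one-tailed greater and the
    down overlap one-tailed less, asking whether the treatment pushes the
    module up more, and down less, than chance.
    """
    universe = set(de_table["gene"]) & background
    mapped = module & universe
    if not mapped:
        raise ValueError("no module genes mapped into the DE table")
    sig = de_table[de_table["padj"].astype(float) < fdr_cut]
    up = set(sig.loc[sig["log2fc"].astype(float) > 0, "gene"]) & universe
    down = set(sig.loc[sig["log2fc"].astype(float) < 0, "gene"]) & universe
    up_fraction = len(mapped & up) / len(mapped)
    down_fraction = len(mapped & down) / len(mapped)
    res_up = _directional_fet(mapped, up, universe, alternative="greater")
    res_down = _directional_fet(mapped, down, universe, alternative="less")
    return up_fraction, down_fraction, res_up, res_down
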