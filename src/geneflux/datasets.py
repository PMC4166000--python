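"""Bundled reference data.

``load_reference_rates`` returns the published per-substitution rates of the
four genome-dynamics event types (gain, loss, expansion, reduction; per site
and per gene) for 35 groups of closely related prokaryote genomes. Used by
the acceptance checks and as a realistic cross-dataset panel for the
comparative statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_rates", "SITE_RATE_COLUMNS", "GENE_RATE_COLUMNS"]

SITE_RATE_COLUMNS = ["gain_site", "loss_site", "expansion_site", "reduction_site"]
GENE_RATE_COLUMNS = ["gain_gene", "loss_gene", "expansion_gene", "reduction_gene"]


def load_reference_rates() -> pd.DataFrame:
    """35 rows x (group id, genera, 4 per-site rates, 4 per-gene rates)."""
    with resources.files("geneflux.data").joinpath("atgc_gde_rates.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
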