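"""Small built-in datasets.

``ripening_candidate_correlations`` carries the published guide-gene
correlation coefficients of three transcription-factor candidates
(FaTCP11, FaPCL1-like, FaSCL8) from a ripening strawberry F1 population,
together with the guide genes' RPKM ranges. Cells are NaN where the
candidate showed no positive correlation with that pathway step; printed
entries all passed the r > 0.65, P < 0.05 filter at 11 degrees of freedom.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Transcript identifiers of the three characterised candidates.
CANDIDATE_GENE_IDS = {
    "FaTCP11": "gene09614",
    "FaPCL1-like": "gene17673",
    "FaSCL8": "gene13212",
}

CANDIDATE_NAMES = tuple(CANDIDATE_GENE_IDS)


def ripening_candidate_correlations() -> pd.DataFrame:
    """Guide role x candidate correlation table with guide RPKM columns.

    Index: pathway roles (PAL1 ... F3H). Columns FaTCP11, FaPCL1-like and
    FaSCL8 hold Pearson coefficients (NaN = no positive correlation);
    rpkm_min / rpkm_max / rpkm_avg are the guide transcripts' RPKM
    statistics across the population.
    """
    ref = resources.files("tcna.data") / "ripening_guide_tf_correlations.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df


def candidate_correlation_row(candidate: str) -> dict[str, float]:
    """role -> r map for one candidate, omitting absent cells (the input
    shape ``count_positive_links`` consumes)."""
    df = ripening_candidate_correlations()
    if candidate not in df.columns:
        raise KeyError(f"unknown candidate {candidate!r}; "
                       f"have {CANDIDATE_NAMES}")
    col = df[candidate].dropna()
    return {role: float(v) for role, v in col.items()}
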