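"""Recompute the published cross-tabulation statistics from the fixtures.

Loads the six embedded 4x4 Deauville cross-tabulations (54 lymphoma
examinations scored under a sharp BSREM-like setting and two EARL-
harmonized settings), then recomputes discordance counts, responder-
boundary crossings and the pairwise Wilcoxon signed-rank p-values.
"""

from petharmony import load_table1
from petharmony.stats import (
    bonferroni,
    discordance_count,
    major_discordance_count,
    pairs_from_crosstab,
    wilcoxon_signed_rank,
)

tables = load_table1()
print(f"Bonferroni-corrected significance level: {bonferroni(0.05, 3)}\n")
for panel, table in tables.items():
    count, frac = discordance_count(table)
    major = major_discordance_count(table)
    test = wilcoxon_signed_rank(pairs_from_crosstab(table))
    print(f"Panel {panel}: {table.metric}, {table.row_method} vs {table.col_method}")
    print(table.to_dataframe().to_string())
    print(
        f"  discordant {count}/{table.total} ({100 * frac:.1f}%), "
        f"responder-boundary crossings {major}, "
        f"Wilcoxon z = {test.z_value:.3f}, p = {test.p_value:.4g}\n"
    )
print(
    "Discordant examinations score LOWER under the EARL settings: the\n"
    "harmonized (smoother) reconstructions recover less uptake in small\n"
    "lesions, shifting scores down relative to the sharp reconstruction."
)
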