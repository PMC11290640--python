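"""Published GDSC2 BRCA IC50 validation screen: the printed summary rows.

The validation screen of the BRCA drug panel against the GDSC2 cell-line
collection reports, for each candidate gene × drug pair, the three
consensus-test p-values (Welch t, Mann-Whitney, Brown–Mood median) and the
mutated / unmutated group sizes.  The six printed rows are reproduced here
as ready-made ``GroupComparison`` records so the consensus calling rule can
be exercised on real published numbers: the strict rule admits ERBB2 and
PIK3CA; the relaxed rule admits all six genes.
"""

from __future__ import annotations

from .snv import GroupComparison

__all__ = ["GDSC_BRCA_IC50_ROWS", "gdsc_brca_ic50_comparisons"]

# gene, drug, p.t, p.w, p.m, no. mutated, no. unmutated
GDSC_BRCA_IC50_ROWS = (
    ("FOXA1", "paclitaxel", 0.011, 0.037, 0.157, 2, 937),
    ("BAP1", "paclitaxel", 0.011, 0.014, 0.068, 15, 924),
    ("NTRK3", "tamoxifen", 0.025, 0.055, 0.014, 6, 932),
    ("ERBB2", "gemcitabine", 0.031, 0.032, 0.019, 15, 927),
    ("ETV6", "tamoxifen", 0.053, 0.034, 0.033, 8, 930),
    ("PIK3CA", "5-fluorouracil", 0.085, 0.049, 0.009, 94, 855),
)


def gdsc_brca_ic50_comparisons() -> list[GroupComparison]:
    """The printed rows as GroupComparison records (measure IC50).

    Group means are not printed for these rows, so they are left NaN; the
    consensus rule needs only the p-value triple and group sizes.
    """
    return [
        GroupComparison(
            target=gene, drug=drug, measure="IC50",
            n_mut=n_mut, n_unmut=n_unmut,
            p_t=p_t, p_w=p_w, p_m=p_m,
        )
        for gene, drug, p_t, p_w, p_m, n_mut, n_unmut in GDSC_BRCA_IC50_ROWS
    ]
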