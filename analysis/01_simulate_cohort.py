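#!/usr/bin/env python
"""Simulate a two-panel screening cohort with planted gene-drug effects.

Writes the three standard inputs (SNV matrix, copy-number matrix, long
response table), a panel configuration, and the planted ground truth under
results/cohort/, so the later screening steps run on files exactly as they
would on a real export.
"""

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from pgxscreen.simulate import (
    CohortSpec,
    CnvEffect,
    SnvEffect,
    SyntheticTruth,
    generate_cohort,
    write_cohort,
)

OUT = Path("results/cohort")
SEED = 20240731

SPEC = CohortSpec(
    n_samples=300,
    genes=(
        ("BRAF", 0.30), ("NRAS", 0.20), ("CDKN2A", 0.25), ("MAP2K1", 0.10),
        ("TP53", 0.30), ("PIK3CA", 0.20), ("ERBB2", 0.10), ("SALL4", 0.08),
        ("GRIN2A", 0.15), ("FAT4", 0.15),
    ),
    drugs=("dabrafenib", "trametinib", "vemurafenib", "dacarbazine", "vindesine"),
    measures=("AUC", "EC50", "LFC"),
    seed=SEED,
)

# effects emulate a BRAF-driven melanoma-like panel: MAPK-pathway mutations
# sensitize to RAF/MEK inhibition on several measures
TRUTH = SyntheticTruth(
    snv_effects=(
        SnvEffect("BRAF", "dabrafenib", "AUC", 1.5, "sensitizing"),
        SnvEffect("BRAF", "dabrafenib", "EC50", 1.5, "sensitizing"),
        SnvEffect("BRAF", "vemurafenib", "AUC", 1.2, "sensitizing"),
        SnvEffect("NRAS", "trametinib", "EC50", 1.2, "sensitizing"),
        SnvEffect("CDKN2A", "dacarbazine", "AUC", 1.0, "resistant"),
        SnvEffect("TP53", "vindesine", "LFC", 1.2, "sensitizing"),
    ),
    cnv_effects=(
        CnvEffect("ERBB2", "vindesine", "AUC", 0.25),
    ),
)


def main():
    mut, cnv, resp, truth = generate_cohort(SPEC, TRUTH)
    paths = write_cohort(mut, cnv, resp, OUT)

    panel = {
        "cancer": "SYN_SKCM",
        "drugs": list(SPEC.drugs),
        "driver_genes": [g for g, _ in SPEC.genes],
        "measures": list(SPEC.measures),
    }
    (OUT / "panels.yaml").write_text(yaml.safe_dump({"panels": [panel]}))
    (OUT / "truth.json").write_text(json.dumps(asdict(truth), indent=1))

    print(f"wrote cohort of {SPEC.n_samples} samples x {len(SPEC.genes)} genes, "
          f"{len(SPEC.drugs)} drugs x {len(SPEC.measures)} measures -> {OUT}")
    print(f"planted {len(TRUTH.snv_effects)} SNV effects and "
          f"{len(TRUTH.cnv_effects)} CNV effect(s); truth in truth.json")
    for k, v in paths.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
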