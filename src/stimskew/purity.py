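"""Marker-panel purity assessment of a sorted cell population.

A sorted preparation (e.g. FACS-isolated microglia) passes when every
lineage-signature marker is expressed above a detection threshold in
enough samples and every contaminant-class marker (astrocyte,
oligodendrocyte, neuron, ...) stays below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MarkerPanel", "purity_report"]


@dataclass
class MarkerPanel:
    """Expected-present and expected-absent marker sets.

    ``expected_present`` maps a class name (e.g. ``"microglia"``) to its
    signature genes; ``expected_absent`` maps each contaminant class to
    its markers.  ``threshold`` is the detection cutoff in the expression
    matrix's units (FPKM or CPM).
    """

    expected_present: dict
    expected_absent: dict
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if not self.expected_present or not self.expected_absent:
            raise ValueError("marker panel must define present and absent sets")
        for name, genes in {**self.expected_present, **self.expected_absent}.items():
            if not genes:
                raise ValueError(f"marker set {name!r} is empty")
        present = {g for gs in self.expected_present.values() for g in gs}
        absent = {g for gs in self.expected_absent.values() for g in gs}
        both = present & absent
        if both:
            raise ValueError(f"markers in both roles: {sorted(both)}")


def purity_report(
    expr: pd.DataFrame,
    panel: MarkerPanel,
    frac_samples: float = 1.0,
) -> dict:
    """Evaluate a marker panel against an expression matrix.

    ``expr`` is genes x samples in the panel's units.  PASS requires every
    present-marker above threshold in >= ``frac_samples`` of samples and
    every absent-marker below it in >= ``frac_samples``.  Panel genes
    missing from the matrix are reported as ``not quantified`` and skipped
    in the verdict.

    Returns a dict with ``verdict`` ("PASS"/"FAIL"), per-class verdicts,
    per-marker detail rows and the list of failing markers.
    """
    if not 0 < frac_samples <= 1:
        raise ValueError("frac_samples must be in (0, 1]")
    n = expr.shape[1]
    rows, failing = [], []
    classes: dict = {}
    for role, sets in (("present", panel.expected_present), ("absent", panel.expected_absent)):
        for cls, genes in sets.items():
            cls_ok = True
            for g in genes:
                if g not in expr.index:
                    rows.append(
                        {"marker": g, "class": cls, "role": role,
                         "status": "not quantified", "frac_detected": np.nan}
                    )
                    continue
                detected = (expr.loc[g] > panel.threshold).to_numpy()
                frac = detected.mean() if n else 0.0
                if role == "present":
                    ok = frac >= frac_samples
                else:
                    ok = (1.0 - frac) >= frac_samples
                rows.append(
                    {"marker": g, "class": cls, "role": role,
                     "status": "ok" if ok else "fail", "frac_detected": frac}
                )
                if not ok:
                    cls_ok = False
                    failing.append(g)
            classes[cls] = "PASS" if cls_ok else "FAIL"
    return {
        "verdict": "PASS" if not failing else "FAIL",
        "classes": classes,
        "failing_markers": failing,
        "markers": pd.DataFrame(rows),
        "threshold": panel.threshold,
        "frac_samples": frac_samples,
    }
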