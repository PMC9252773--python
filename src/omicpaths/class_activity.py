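"""Metabolite class activity analysis.

Tests whether a metabolite class contains a higher-than-expected fraction
of significant compounds: one-sided exact binomial upper tail
P(X >= n_significant), X ~ Binomial(n_measured, threshold). When the user
gives no activity threshold, the overall fraction of significant measured
metabolites serves as the null proportion. Classes may overlap (chemical
taxonomies do); each class is tested independently and BH correction is
applied across the tested classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .model import OmicsDataset
from .stats import adjust_bh, binomial_tail


@dataclass
class ClassActivityResult:
    class_name: str
    n_measured: int
    n_significant: int
    threshold_used: float
    p: float | None
    adjusted_p: float | None
    reason: str = ""


def class_activity_test(n_significant: int, n_measured: int, threshold: float) -> float:
    """Upper-tail exact binomial P for a class's significant-compound count."""
    return binomial_tail(n_significant, n_measured, threshold)


def run_class_activity(
    metabolite_dataset: OmicsDataset,
    class_map: Mapping[str, set[str]],
    threshold: float | None = None,
) -> list[ClassActivityResult]:
    """Binomial class activity test for every class with measured members.

    ``class_map`` maps class name → metabolite ids. Metabolites absent
    from every class still contribute to the default threshold (the
    overall significant fraction). Classes with no measured member are
    returned flagged and excluded from the BH correction.
    """
    measured = metabolite_dataset.ids
    if not measured:
        raise ConfigurationError("metabolite layer has no measured features")
    significant = metabolite_dataset.significant_ids

    if threshold is None:
        threshold = len(significant) / len(measured)
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(
            f"activity threshold {threshold} is outside (0, 1); pass an explicit "
            "--threshold when all or none of the metabolites are significant"
        )

    results: list[ClassActivityResult] = []
    for cls in sorted(class_map):
        members = class_map[cls] & measured
        if not members:
            results.append(
                ClassActivityResult(
                    class_name=cls,
                    n_measured=0,
                    n_significant=0,
                    threshold_used=threshold,
                    p=None,
                    adjusted_p=None,
                    reason="no measured members",
                )
            )
            continue
        k = len(members & significant)
        results.append(
            ClassActivityResult(
                class_name=cls,
                n_measured=len(members),
                n_significant=k,
                threshold_used=threshold,
                p=class_activity_test(k, len(members), threshold),
                adjusted_p=None,
            )
        )

    tested = [r for r in results if r.p is not None]
    if not tested:
        raise ConfigurationError("no class contains any measured metabolite")
    adjusted = adjust_bh([r.p for r in tested])
    for r, adj in zip(tested, adjusted):
        r.adjusted_p = float(adj)

    results.sort(
        key=lambda r: (
            r.adjusted_p if r.adjusted_p is not None else 2.0,
            r.p if r.p is not None else 2.0,
            r.class_name,
        )
    )
    return results


def class_activity_frame(results: Sequence[ClassActivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": r.class_name,
                "n_measured": r.n_measured,
                "n_significant": r.n_significant,
                "threshold_used": r.threshold_used,
                "p": r.p,
                "adjusted_p": r.adjusted_p,
                "note": r.reason,
            }
            for r in results
        ]
    )
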