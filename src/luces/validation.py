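"""Map-agreement metrics and the backcasting harness.

Simulated maps are judged against reference maps by plain cell-by-cell
percent agreement (the published metric for this model family), with a
class-by-class confusion matrix and Cohen's kappa as secondary outputs.
Backcasting runs the simulator from a historical map under an ensemble of
seeds and reports the distribution of end-state agreement with the observed
later map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .landscape import LandCover, LandscapeGrid


@dataclass
class AgreementReport:
    overall_percent: float
    per_class_agreement: dict[LandCover, float]
    confusion: np.ndarray  # class x class cell counts, index = LandCover order
    kappa: float
    classes: tuple[LandCover, ...] = tuple(LandCover)

    def confusion_frame(self):
        import pandas as pd

        labels = [c.label for c in self.classes]
        return pd.DataFrame(self.confusion, index=labels, columns=labels)


def map_similarity(map_a: LandscapeGrid, map_b: LandscapeGrid) -> AgreementReport:
    """Cell-by-cell agreement between two land-cover maps.

    ``overall_percent = 100 * (#cells with equal class) / (#cells)``.  The
    confusion matrix counts cells by (class in A, class in B); its trace over
    the total recovers the overall percentage.  Per-class agreement is the
    recall of each class of A.  Kappa corrects agreement for chance and is
    reported as a secondary statistic.
    """
    if map_a.cover.shape != map_b.cover.shape:
        raise ValueError(
            f"dimension mismatch: {map_a.cover.shape} vs {map_b.cover.shape}"
        )
    classes = tuple(LandCover)
    k = len(classes)
    code_to_idx = {int(c): i for i, c in enumerate(classes)}
    a = np.vectorize(code_to_idx.get)(map_a.cover.ravel())
    b = np.vectorize(code_to_idx.get)(map_b.cover.ravel())
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (a, b), 1)
    total = confusion.sum()
    agree = np.trace(confusion)
    overall = 100.0 * agree / total
    per_class = {}
    for i, c in enumerate(classes):
        row_total = confusion[i].sum()
        per_class[c] = float(confusion[i, i] / row_total) if row_total else float("nan")
    pe = float((confusion.sum(axis=0) / total) @ (confusion.sum(axis=1) / total))
    po = agree / total
    kappa = (po - pe) / (1 - pe) if pe < 1.0 else 1.0
    return AgreementReport(
        overall_percent=float(overall),
        per_class_agreement=per_class,
        confusion=confusion,
        kappa=float(kappa),
        classes=classes,
    )


@dataclass
class BackcastResult:
    similarities: list[float]
    median: float
    min: float
    max: float
    reports: list[AgreementReport]


def backcast(
    config,
    start_map: LandscapeGrid,
    reference_map: LandscapeGrid,
    n_seeds: int,
) -> BackcastResult:
    """Hindcast validation: simulate forward from a historical map.

    Runs ``n_seeds`` simulations (seeds ``config.seed .. config.seed +
    n_seeds - 1``) starting from ``start_map`` and reports the percent
    agreement of each final map with ``reference_map``.  The reference year
    must equal the start year plus the simulated horizon.
    """
    from .dynamics import run_simulation

    if reference_map.year != start_map.year + config.n_years:
        raise ValueError(
            "reference map year must equal start year + n_years "
            f"({start_map.year} + {config.n_years} != {reference_map.year})"
        )
    sims: list[float] = []
    reports: list[AgreementReport] = []
    for i in range(n_seeds):
        cfg = replace(config, seed=config.seed + i, initial_grid=start_map)
        result = run_simulation(cfg)
        report = map_similarity(result.final_grid, reference_map)
        reports.append(report)
        sims.append(report.overall_percent)
    return BackcastResult(
        similarities=sims,
        median=float(np.median(sims)),
        min=float(np.min(sims)),
        max=float(np.max(sims)),
        reports=reports,
    )
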