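"""Source-model calibration against reference depth-dose / profile data.

The optimizer is a deterministic coordinate descent over a user-declared
grid, with a lexicographic objective: first the RMS relative difference of
the six depth-dose reference points, then the profile symmetry and
homogeneity differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .analysis import PddReferencePoints, ProfileMetrics
from .source import BeamSourceModel

__all__ = ["MatchReport", "compare", "calibrate_source"]

RMS_TOL = 2.0  # %
SYM_TOL = 3.0  # %
HOM_TOL = 5.0  # %

_REF_FIELDS = ("r100", "r90", "r50", "r30", "r10", "rp")


@dataclass(frozen=True)
class MatchReport:
    """Agreement between simulated and reference curves."""

    rms_relative_diff_pdd_refs: float  # % over R100,R90,R50,R30,R10,Rp
    symmetry_diff: float  # absolute %
    homogeneity_diff: float  # absolute %
    passed: bool

    def objective(self) -> tuple[float, float, float]:
        return (
            self.rms_relative_diff_pdd_refs,
            self.symmetry_diff,
            self.homogeneity_diff,
        )


def compare(
    sim_refs: PddReferencePoints,
    ref_refs: PddReferencePoints,
    sim_profile: ProfileMetrics | None = None,
    ref_profile: ProfileMetrics | None = None,
) -> MatchReport:
    """RMS relative PDD-reference difference plus profile parameter diffs."""
    diffs = []
    for name in _REF_FIELDS:
        s = getattr(sim_refs, name)
        r = getattr(ref_refs, name)
        if not (np.isfinite(s) and np.isfinite(r)):
            raise ValueError(f"missing reference point {name!r}")
        diffs.append((s - r) / r)
    rms = 100.0 * float(np.sqrt(np.mean(np.square(diffs))))
    if (sim_profile is None) != (ref_profile is None):
        raise ValueError("profile metrics must be given for both sides or neither")
    if sim_profile is not None:
        sym_d = abs(sim_profile.symmetry - ref_profile.symmetry)
        hom_d = abs(sim_profile.homogeneity - ref_profile.homogeneity)
    else:
        sym_d = hom_d = 0.0
    passed = rms <= RMS_TOL and sym_d <= SYM_TOL and hom_d <= HOM_TOL
    return MatchReport(rms, sym_d, hom_d, passed)


def calibrate_source(
    base: BeamSourceModel,
    ref_refs: PddReferencePoints,
    search_space: dict[str, list[float]],
    budget: int,
    evaluate,
    ref_profile: ProfileMetrics | None = None,
):
    """Coordinate descent over a parameter grid.

    ``evaluate(model) -> (PddReferencePoints, ProfileMetrics | None)`` runs
    whatever simulation backs the calibration (injectable for testing).
    Returns ``(best_model, trace, best_report)``; if the budget runs out
    without a pass the best-so-far is returned flagged ``passed=False``.
    Trace entries are ``(params_dict, MatchReport)`` in evaluation order and
    the running best objective is monotone non-increasing.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    for key in search_space:
        if not hasattr(base, key):
            raise ValueError(f"unknown source parameter {key!r}")

    cache: dict[tuple, MatchReport] = {}
    trace: list[tuple[dict, MatchReport]] = []
    evals = 0

    def params_of(model: BeamSourceModel) -> dict:
        return {k: getattr(model, k) for k in search_space}

    def run(model: BeamSourceModel) -> MatchReport | None:
        nonlocal evals
        key = tuple(sorted(params_of(model).items()))
        if key in cache:
            return cache[key]
        if evals >= budget:
            return None
        evals += 1
        sim_refs, sim_prof = evaluate(model)
        rep = compare(sim_refs, ref_refs, sim_prof, ref_profile)
        cache[key] = rep
        trace.append((params_of(model), rep))
        return rep

    best_model = base
    best_rep = run(base)
    improved = True
    while improved and evals < budget:
        improved = False
        for key, values in search_space.items():
            for v in values:
                if v == getattr(best_model, key):
                    continue
                cand = replace(best_model, **{key: v})
                rep = run(cand)
                if rep is None:
                    break
                if best_rep is None or rep.objective() < best_rep.objective():
                    best_model, best_rep = cand, rep
                    improved = True
            if evals >= budget:
                break
    if best_rep is None:
        raise RuntimeError("budget exhausted before any evaluation completed")
    return best_model, trace, best_rep
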