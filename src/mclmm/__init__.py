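"""mclmm: exact linear-time linear mixed models for multi-context studies.

Fits the LMM ``y = X beta + u + e`` with ``u ~ N(0, sigma_g^2 K)`` where K
is the within-individual indicator matrix of a multiple-context design
(multi-tissue eQTL, multi-phenotype GWAS), using a likelihood refactoring
that avoids any N x N eigendecomposition, plus an exact closed form when
no observations are missing, and a correlated fixed-effects meta-analysis
of the per-context effects.
"""

from .closed_form import (
    ResidualSummary,
    delta_closed_form,
    fit_complete,
    per_context_ols,
    residual_summary,
)
from .data_model import (
    CollinearityError,
    FitResult,
    GroupIndex,
    MultiContextData,
    StackedDesign,
    build_group_index,
    stack_design,
    unstack_design,
)
from .likelihood_general import (
    DegenerateResidualError,
    fit_general,
    log_det_H,
    neg_loglik,
    residual_terms,
    xtHx,
)
from .meta import (
    ContextEffects,
    MetaResult,
    effect_correlation,
    fixed_effects_meta,
    meta_analyze_fit,
)
from .simulate import (
    SimScenario,
    apply_sampling_mask,
    draw_effects,
    simulate_effect_responses,
    simulate_genotypes,
    simulate_null_responses,
)

__version__ = "0.1.0"


def fit(data: MultiContextData, method: str = "REML", **kwargs) -> FitResult:
    """Fit the multi-context LMM, dispatching on missingness.

    Complete data take the exact non-iterative solver; any missing
    response routes to the general iterative solver.
    """
    if data.is_complete:
        kwargs.pop("tol", None)
        return fit_complete(data, method, **kwargs)
    return fit_general(data, method, **kwargs)


__all__ = [
    "CollinearityError",
    "ContextEffects",
    "DegenerateResidualError",
    "FitResult",
    "GroupIndex",
    "MetaResult",
    "MultiContextData",
    "ResidualSummary",
    "SimScenario",
    "StackedDesign",
    "apply_sampling_mask",
    "build_group_index",
    "delta_closed_form",
    "draw_effects",
    "effect_correlation",
    "fit",
    "fit_complete",
    "fit_general",
    "fixed_effects_meta",
    "log_det_H",
    "meta_analyze_fit",
    "neg_loglik",
    "per_context_ols",
    "residual_summary",
    "residual_terms",
    "simulate_effect_responses",
    "simulate_genotypes",
    "simulate_null_responses",
    "stack_design",
    "unstack_design",
    "xtHx",
]
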