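"""Backward elimination over simultaneous exposure x modifier interactions.

Starting from a model that enters every candidate product term at once, the
term with the largest Wald p-value is dropped and the model refitted, until
every remaining product term has p < alpha (default 0.05) or none remain.
Moderator main effects implied by the model are never candidates — only the
product terms are eliminated.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .effects import interaction_test, product_terms
from .glm import ModelSpec, build_design, fit_quasipoisson


@dataclass(frozen=True)
class SelectionStep:
    terms: tuple          # candidate moderators still in the model
    p_values: dict        # moderator -> Wald p at this step
    dropped: str | None   # moderator removed after this step


@dataclass
class SelectionTrace:
    steps: list
    final_terms: frozenset
    alpha: float
    final_fit: object = None

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for k, step in enumerate(self.steps):
            for term in sorted(step.terms):
                rows.append({
                    "step": k, "term": term, "p_value": step.p_values[term],
                    "action": "dropped" if term == step.dropped else
                              ("retained" if step.dropped is None else "kept"),
                })
        return pd.DataFrame(rows, columns=["step", "term", "p_value", "action"])


def _default_fitter(panel, spec):
    """Fit the joint interaction model and return per-moderator Wald p-values.

    Scalar moderators contribute a 1-df product term; spline moderators a
    joint chi-square over their two product columns.
    """
    def fitter(moderators):
        full = replace(spec, interactions=tuple(moderators))
        fit = fit_quasipoisson(build_design(panel, full))
        ps = {m: interaction_test(fit, product_terms(fit, m)).p_value
              for m in moderators}
        return ps, fit
    return fitter


def backward_eliminate(panel: pd.DataFrame | None, spec: ModelSpec | None,
                       candidates, alpha: float = 0.05,
                       fitter=None) -> SelectionTrace:
    """Run the elimination and return the full trace.

    ``fitter`` (injectable for testing) maps a tuple of candidate moderators
    to ``(p_values, fit)``; the default fits the joint quasi-Poisson model.
    Ties in the largest p-value are broken lexicographically by name.
    """
    candidates = tuple(candidates)
    if fitter is None:
        fitter = _default_fitter(panel, spec or ModelSpec())
    steps = []
    terms = candidates
    fit = None
    while terms:
        result = fitter(terms)
        ps, fit = result if isinstance(result, tuple) else (result, None)
        worst = max(ps.values())
        if worst < alpha:
            steps.append(SelectionStep(terms=terms, p_values=dict(ps), dropped=None))
            break
        drop = min(t for t in terms if ps[t] == worst)
        steps.append(SelectionStep(terms=terms, p_values=dict(ps), dropped=drop))
        terms = tuple(t for t in terms if t != drop)
        fit = None
    return SelectionTrace(steps=steps, final_terms=frozenset(terms),
                          alpha=alpha, final_fit=fit)
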