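"""End-to-end screen pipeline: traces → per-well fits → planned comparisons.

Glue that runs the screen the way the bench protocol does: every well's
quench trace is fitted in constrained mode (transient conductance fixed to
the DMSO-control averages), per-well conductances and per-cell ρ values are
assembled, and the planned variant-versus-reference comparisons are adjusted
by Benjamini–Hochberg at a 10 % FDR.
"""

from __future__ import annotations

import pandas as pd

from .plate_stats import screen_comparisons
from .quench_model import ProtocolSpec, standard_protocol
from .synthetic_data import PlateDataset, PlateSpec, make_plate
from .trace_fit import fit_trace

__all__ = ["fit_screen_traces", "run_screen", "simulate_screen"]


def fit_screen_traces(
    dataset: PlateDataset,
    *,
    protocol_fsk: ProtocolSpec | None = None,
    protocol_dmso: ProtocolSpec | None = None,
    variants=None,
    conditions=("forskolin",),
    mode: str = "constrained",
    **fit_kw,
) -> pd.DataFrame:
    """Fit every (selected) well trace; one row per well.

    ``variants``/``conditions`` restrict which traces are fitted (None means
    all); restricting is useful when only some groups enter the statistics.
    """
    protocol_fsk = protocol_fsk or standard_protocol(True)
    protocol_dmso = protocol_dmso or standard_protocol(False)
    rows = []
    for trace in dataset.traces:
        if variants is not None and trace.genotype not in variants:
            continue
        if conditions is not None and trace.condition not in conditions:
            continue
        proto = protocol_fsk if trace.condition == "forskolin" else protocol_dmso
        res = fit_trace(trace, proto, mode=mode, **fit_kw)
        rows.append({
            "plate": trace.plate, "well": trace.well,
            "variant": trace.genotype, "condition": trace.condition,
            "G_hat": res.G_hat, "Vm_hat": res.Vm_hat,
            "residual_ss": res.residual_ss, "converged": res.converged,
        })
    return pd.DataFrame(rows)


def run_screen(
    dataset: PlateDataset,
    *,
    reference: str = "F508del",
    wt: str = "WT",
    q: float = 0.10,
    fit_variants=None,
    **fit_kw,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full analysis of one simulated or imported screen dataset.

    Returns (fits, stats): per-well fit results and the BH-adjusted planned
    comparisons. ``fit_variants=None`` fits every variant; passing the subset
    entering the statistics saves time on large screens.
    """
    fits = fit_screen_traces(dataset, variants=fit_variants, **fit_kw)
    stats = screen_comparisons(fits, dataset.rho_cells,
                               reference=reference, wt=wt, q=q)
    return fits, stats


def simulate_screen(
    spec: PlateSpec,
    seed: int,
    *,
    q: float = 0.10,
    fit_test_variants_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one screen from ``spec`` and analyze it end to end.

    With ``fit_test_variants_only`` the conductance fits cover the reference
    and the test variants (what the comparisons consume); WT wells still
    anchor the ρ normalization inside the generator.
    """
    dataset = make_plate(spec, seed=seed, conditions=("forskolin",))
    fit_variants = None
    if fit_test_variants_only:
        fit_variants = {v.name for v in spec.variants if v.name != spec.wt_name}
    return run_screen(dataset, reference=spec.reference_name, wt=spec.wt_name,
                      q=q, fit_variants=fit_variants)
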