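"""Per-gene and per-table orchestration of the three-model comparison.

Thin functional wrappers over :class:`tempshift.estimator.TempShiftGP`:
``fit_gene`` runs one gene, ``fit_table`` runs a genes x samples
expression table against its sample metadata and collects one
:class:`~tempshift.data.GeneResult` per gene.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import GeneResult, GeneSeries
from .estimator import TempShiftGP

__all__ = ["fit_gene", "fit_table", "results_to_frame"]

logger = logging.getLogger(__name__)

#: a gene is skipped (left unclassified) if any group keeps fewer points
MIN_POINTS_PER_GROUP = 3


def _estimator_kwargs(settings: dict | None) -> dict:
    return dict(settings or {})


def fit_gene(gene: GeneSeries, reference_group=None, settings: dict | None = None) -> GeneResult:
    """Fit all three models to one gene and compute its LLRs.

    The class label is left unset; classification is a separate stage
    operating on a whole cohort's LLR distribution.
    """
    if gene.n_groups < 2:
        raise ValueError(f"gene {gene.gene!r}: at least two groups are required")
    est = TempShiftGP(reference=reference_group, **_estimator_kwargs(settings))
    t = gene.times.pooled
    g = np.repeat(np.array(gene.times.labels, dtype=object), gene.times.sizes)
    X = pd.DataFrame({"time": t, "group": g})
    est.fit(X, gene.pooled_values)
    ll = est.log_likelihoods_
    return GeneResult(
        gene=gene.gene,
        group_labels=est.groups_,
        logl_independence=ll.get("independence", np.nan),
        logl_no_shift=ll.get("no_shift", np.nan),
        logl_shift=ll.get("shift", np.nan),
        llr_shape=est.llr_shape_,
        llr_shift=est.llr_shift_,
        shifts=est.shifts_,
        kernel_params=est.kernel_params_,
        converged=est.converged_,
    )


def _skipped(gene_id, labels, note) -> GeneResult:
    logger.warning("gene %s skipped: %s", gene_id, note)
    return GeneResult(gene=gene_id, group_labels=tuple(labels), label="unclassified", note=note)


def fit_table(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    reference_group=None,
    settings: dict | None = None,
    min_points: int = MIN_POINTS_PER_GROUP,
    progress_callback=None,
) -> list[GeneResult]:
    """Fit every gene of an expression table; order is preserved.

    Parameters
    ----------
    expression : DataFrame
        Genes x samples, index = gene identifiers, columns = sample
        identifiers; NaN marks missing values (dropped per gene).
    metadata : DataFrame
        Indexed by sample identifier with columns ``group`` and ``time``;
        every expression column must be present.
    reference_group : hashable, optional
        Reference (Δt = 0) group; default is the first group in metadata
        order.
    min_points : int
        A gene is skipped if, after dropping its missing samples, any
        group retains fewer observations than this.
    progress_callback : callable, optional
        Called once per finished gene (for CLI progress display).
    """
    missing = [c for c in expression.columns if c not in metadata.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    meta = metadata.loc[list(expression.columns)]
    group_order = list(dict.fromkeys(meta["group"]))
    if reference_group is None:
        reference_group = group_order[0]
    elif reference_group not in group_order:
        raise ValueError(f"reference group {reference_group!r} not in metadata")

    times = meta["time"].to_numpy(dtype=float)
    groups = meta["group"].to_numpy()

    results: list[GeneResult] = []
    for gene_id, row in expression.iterrows():
        vals = row.to_numpy(dtype=float)
        keep = np.isfinite(vals)
        n_dropped = int((~keep).sum())
        g_kept = groups[keep]
        counts = {lab: int((g_kept == lab).sum()) for lab in group_order}
        if any(c < min_points for c in counts.values()):
            results.append(
                _skipped(gene_id, group_order, f"a group has < {min_points} usable samples")
            )
        else:
            X = pd.DataFrame({"time": times[keep], "group": g_kept})
            est = TempShiftGP(reference=reference_group, **_estimator_kwargs(settings))
            est.fit(X, vals[keep])
            note = f"dropped {n_dropped} missing samples" if n_dropped else ""
            if not all(est.converged_.values()):
                bad = [k for k, v in est.converged_.items() if not v]
                logger.warning("gene %s: %s fit did not converge", gene_id, bad)
            ll = est.log_likelihoods_
            results.append(
                GeneResult(
                    gene=gene_id,
                    group_labels=est.groups_,
                    logl_independence=ll.get("independence", np.nan),
                    logl_no_shift=ll.get("no_shift", np.nan),
                    logl_shift=ll.get("shift", np.nan),
                    llr_shape=est.llr_shape_,
                    llr_shift=est.llr_shift_,
                    shifts=est.shifts_,
                    kernel_params=est.kernel_params_,
                    converged=est.converged_,
                    note=note,
                )
            )
        if progress_callback is not None:
            progress_callback()
    return results


def results_to_frame(results: list[GeneResult]) -> pd.DataFrame:
    """Flatten GeneResults into the tabular results layout.

    Shift columns are named ``dt_<group>`` for every non-reference group
    of the first classifiable result.
    """
    labels = None
    for r in results:
        if r.shifts is not None:
            labels = r.group_labels
            break
    if labels is None and results:
        labels = results[0].group_labels
    rows = []
    for r in results:
        row = {
            "gene_id": r.gene,
            "logl_independence": r.logl_independence,
            "logl_no_shift": r.logl_no_shift,
            "logl_shift": r.logl_shift,
            "llr_shape": r.llr_shape,
            "llr_shift": r.llr_shift,
        }
        if labels is not None:
            for i, lab in enumerate(labels):
                if i == 0:
                    continue
                row[f"dt_{lab}"] = (
                    r.shifts[i] if r.shifts is not None and len(r.shifts) > i else np.nan
                )
        kp = r.kernel_params
        row["sigma_f"] = kp.sigma_f if kp else np.nan
        row["length_scale"] = kp.length_scale if kp else np.nan
        row["noise_sd"] = kp.noise_sd if kp else np.nan
        row["converged"] = all(r.converged.values()) if r.converged else False
        row["label"] = r.label if r.label is not None else ""
        row["note"] = r.note
        rows.append(row)
    return pd.DataFrame(rows)
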