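"""Versioned registry of published limited-sampling equations.

The coefficients of the published equations live in a plain delimited
fixture packaged with the library (``data/published_models.csv``) rather
than as literals scattered through code.  Reported statistics are stored
verbatim and never recomputed; anything this package computes is labelled
"recomputed" in its own columns.  The packaged fixture is checksummed at
load time to catch accidental edits.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import io
from typing import Sequence

import pandas as pd

from .errors import RegistryError
from .lss import bias_precision, predict, predictor_matrix
from .nca import best_estimates
from .types import (
    EXTERNAL,
    CocktailDataset,
    PublishedModelEntry,
    ValidationReport,
    format_times,
    parse_times,
)

#: sha256 of the packaged registry fixture; guards against silent edits.
PACKAGED_SHA256 = "efce6efb1928afbc00f3f7f0bd4ddc04c8c6b9dfcab9bdc74ef8d7b58b2026fc"

_COLUMNS = (
    "probe",
    "metric_kind",
    "source_table",
    "sampling_times",
    "intercept",
    "coefficients",
    "reported_r2",
    "reported_md_mean",
    "reported_md_sd",
    "reported_mad_mean",
    "reported_mad_sd",
)


def _packaged_bytes() -> bytes:
    ref = importlib.resources.files("cocktail_lss").joinpath("data/published_models.csv")
    return ref.read_bytes()


def load_registry(
    path=None, source_table: str | None = "Table2"
) -> list[PublishedModelEntry]:
    """Load published model entries, default from the packaged fixture.

    ``source_table`` filters to one table ("Table2" training equations by
    default); pass ``None`` for every entry.  The packaged fixture must
    match its recorded checksum.
    """
    if path is None:
        raw = _packaged_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        if digest != PACKAGED_SHA256:
            raise RegistryError(
                f"packaged registry checksum mismatch ({digest[:12]}...)"
            )
    else:
        with open(path, "rb") as fh:
            raw = fh.read()
    try:
        frame = pd.read_csv(io.BytesIO(raw), comment="#")
    except Exception as exc:  # malformed file
        raise RegistryError(f"cannot parse registry: {exc}") from exc
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise RegistryError(f"registry missing columns {sorted(missing)}")
    entries = []
    for i, row in frame.iterrows():
        try:
            entry = PublishedModelEntry(
                probe=str(row["probe"]),
                metric_kind=str(row["metric_kind"]),
                sampling_times=parse_times(row["sampling_times"]),
                intercept=float(row["intercept"]),
                coefficients=tuple(
                    float(c) for c in str(row["coefficients"]).split(";")
                ),
                source_table=str(row["source_table"]),
                reported_r2=float(row["reported_r2"]),
                reported_md_mean=float(row["reported_md_mean"]),
                reported_md_sd=float(row["reported_md_sd"]),
                reported_mad_mean=float(row["reported_mad_mean"]),
                reported_mad_sd=float(row["reported_mad_sd"]),
            )
        except Exception as exc:
            raise RegistryError(f"malformed registry row {i + 2}: {exc}") from exc
        entries.append(entry)
    if source_table is not None:
        entries = [e for e in entries if e.source_table == source_table]
    return entries


def save_registry(entries: Sequence[PublishedModelEntry], path) -> None:
    """Write entries back in the registry CSV schema (schema header included)."""
    rows = []
    for e in entries:
        rows.append(
            {
                "probe": e.probe,
                "metric_kind": e.metric_kind,
                "source_table": e.source_table,
                "sampling_times": format_times(e.sampling_times),
                "intercept": repr(e.intercept),
                "coefficients": ";".join(repr(c) for c in e.coefficients),
                "reported_r2": repr(e.reported_r2),
                "reported_md_mean": repr(e.reported_md_mean),
                "reported_md_sd": repr(e.reported_md_sd),
                "reported_mad_mean": repr(e.reported_mad_mean),
                "reported_mad_sd": repr(e.reported_mad_sd),
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# cocktail-lss published limited-sampling model registry, schema=1\n")
        pd.DataFrame(rows, columns=list(_COLUMNS)).to_csv(fh, index=False)


def apply_published(
    entry: PublishedModelEntry,
    dataset: CocktailDataset,
    phase: int = 1,
    exclude_subjects: dict[str, set[int]] | None = None,
) -> ValidationReport:
    """Apply one published equation, frozen, to a dataset phase.

    Predictions from the concentrations (or ratios) at the entry's times
    are compared against the phase's best estimates; the report cites the
    entry's source table.
    """
    exclude_subjects = exclude_subjects or {}
    model = entry.as_model()
    X = predictor_matrix(
        dataset,
        entry.probe,
        phase,
        times=entry.sampling_times,
        exclude_subjects=exclude_subjects.get(entry.probe, set()),
    )
    metrics = best_estimates(dataset, phase, exclude_subjects)
    best = (
        metrics[metrics["probe"] == entry.probe]
        .set_index("subject_id")["value"]
        .reindex(X.index)
    )
    pred = predict(model, X)
    evaluation = bias_precision(pred.to_numpy(), best.to_numpy())
    per_subject = pd.DataFrame(
        {"subject_id": X.index, "best": best.to_numpy(), "predicted": pred.to_numpy()}
    ).reset_index(drop=True)
    return ValidationReport(
        probe=entry.probe,
        metric_kind=entry.metric_kind,
        sampling_times=entry.sampling_times,
        mode=EXTERNAL,
        evaluation=evaluation,
        per_subject=per_subject,
        source=entry.source_table,
    )
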