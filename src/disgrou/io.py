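"""CSV input and TSV/JSON result serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd

from .data_model import DataError, Dataset, Subgroup
from .intervals import IntervalSet, parse_interval_set

__all__ = [
    "ResultRecord",
    "read_csv",
    "write_dataset_csv",
    "write_results",
    "records_from_subgroups",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ResultRecord:
    """One ranked subgroup, ready for serialization.

    The description renders each attribute's interval set with the
    "[a;b] ∪ [c;d]" convention; endpoints keep full precision so parsing a
    rendered description reproduces the IntervalSet exactly.
    """

    rank: int
    quality: float
    n: int
    mean: float
    population_mean: float
    description: Mapping[str, IntervalSet]

    def render_description(self) -> str:
        return " AND ".join(
            f"{a} ∈ {self.description[a]}" for a in sorted(self.description)
        )


def parse_description(text: str) -> dict[str, IntervalSet]:
    out: dict[str, IntervalSet] = {}
    for clause in text.split(" AND "):
        attr, sep, ranges = clause.partition(" ∈ ")
        if not sep:
            raise ValueError(f"malformed description clause: {clause!r}")
        out[attr.strip()] = parse_interval_set(ranges)
    return out


def records_from_subgroups(
    subgroups: Sequence[Subgroup], population_mean: float
) -> list[ResultRecord]:
    return [
        ResultRecord(
            rank=i + 1,
            quality=sub.quality,
            n=sub.n,
            mean=sub.mean,
            population_mean=population_mean,
            description=sub.description,
        )
        for i, sub in enumerate(subgroups)
    ]


# ---------------------------------------------------------------------------
# CSV input


def read_csv(path: PathLike, target_column: str) -> Dataset:
    """Load a numeric table: header row, one target column, the rest attributes.

    Any missing or non-numeric cell aborts the load with the offending row
    and column named; no partial dataset is ever returned.
    """
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise DataError(f"no such file: {path}") from None
    except pd.errors.EmptyDataError:
        raise DataError(f"empty file: {path}") from None
    if target_column not in frame.columns:
        raise DataError(
            f"unknown target column {target_column!r}; "
            f"columns are {list(frame.columns)}"
        )
    attrs = [c for c in frame.columns if c != target_column]
    if not attrs:
        raise DataError("no attributes (the table has only the target column)")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r = int(bad.any(axis=1).idxmax())
        c = bad.columns[bad.loc[r].to_numpy().argmax()]
        raise DataError(
            f"missing or non-numeric value at row {r}, column {c!r}"
        )
    if len(numeric) == 0:
        raise DataError("empty dataset")
    return Dataset(
        attrs,
        numeric[attrs].to_numpy(dtype=float),
        numeric[target_column].to_numpy(dtype=float),
        target_name=target_column,
    )


def write_dataset_csv(dataset: Dataset, path: PathLike) -> None:
    frame = pd.DataFrame(dataset.values, columns=dataset.attribute_names)
    frame[dataset.target_name] = dataset.target
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result output


def _g6(x: float) -> str:
    return format(x, ".6g")


def write_results(
    records: Sequence[ResultRecord], path: PathLike, format: str = "tsv"
) -> None:
    """Write ranked subgroups as TSV (default) or JSON.

    Scores and means carry 6 significant digits; interval endpoints keep
    full precision so the description round-trips.
    """
    path = Path(path)
    if format == "tsv":
        lines = ["rank\tquality\tn\tmean\tpopulation_mean\tdescription"]
        for rec in records:
            lines.append(
                "\t".join(
                    [
                        str(rec.rank),
                        _g6(rec.quality),
                        str(rec.n),
                        _g6(rec.mean),
                        _g6(rec.population_mean),
                        rec.render_description(),
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "json":
        payload = [
            {
                "rank": rec.rank,
                "quality": float(_g6(rec.quality)),
                "n": rec.n,
                "mean": float(_g6(rec.mean)),
                "population_mean": float(_g6(rec.population_mean)),
                "description": {
                    a: str(rec.description[a]) for a in sorted(rec.description)
                },
            }
            for rec in records
        ]
        path.write_text(
            json.dumps(payload, ensure_ascii=False, indent=2) + "\n",
            encoding="utf-8",
        )
    else:
        raise ValueError(f"unknown format {format!r} (expected tsv or json)")


def read_results_tsv(path: PathLike) -> list[ResultRecord]:
    """Parse a TSV written by :func:`write_results` (round-trip helper)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    records = []
    for line in lines[1:]:
        rank, q, n, mean, m0, desc = line.split("\t")
        records.append(
            ResultRecord(
                rank=int(rank),
                quality=float(q),
                n=int(n),
                mean=float(mean),
                population_mean=float(m0),
                description=parse_description(desc),
            )
        )
    return records
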