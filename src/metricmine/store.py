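"""Durable relational logging of campaign runs and metric values.

An embedded single-file sqlite database provides the ACID guarantees the
workflow relies on (a crashed evaluation never leaves a half-written battery)
while remaining queryable ad hoc.  The schema is plain SQL (shipped as
``data/schema.sql``) so a client-server backend is a drop-in replacement.
"""

from __future__ import annotations

import json
import sqlite3
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .campaign import RunRecord
from .metrics import METRIC_ORDER, MetricResult, MetricTable

__all__ = ["MetricStore", "DuplicateRunError", "UnknownRunError", "EmptySelectionError"]


class DuplicateRunError(ValueError):
    pass


class UnknownRunError(KeyError):
    pass


class EmptySelectionError(LookupError):
    """A fetch matched no rows (typed so callers can distinguish it from bugs)."""


def _utcnow() -> str:
    return datetime.now(timezone.utc).isoformat()


class MetricStore:
    """SQLite-backed store of runs and their 11-metric batteries.

    Can be used as a context manager; ``path=":memory:"`` gives an ephemeral
    store for tests and ad hoc analysis.
    """

    def __init__(self, path: Union[str, Path] = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        schema = resources.files("metricmine.data").joinpath("schema.sql").read_text()
        with self._conn:
            self._conn.executescript(schema)

    # -- lifecycle -----------------------------------------------------
    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "MetricStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- writes --------------------------------------------------------
    def log_run(self, record: RunRecord) -> str:
        """Insert one run; rejects duplicate run_ids, leaving the store unchanged."""
        params = json.dumps(record.parameters, sort_keys=True)
        try:
            with self._conn:
                self._conn.execute(
                    "INSERT INTO runs (run_id, algorithm, parameters_json, image_path,"
                    " created_at, status) VALUES (?, ?, ?, ?, ?, ?)",
                    (
                        record.run_id,
                        record.algorithm_name,
                        params,
                        record.image_path,
                        record.created_at,
                        record.status,
                    ),
                )
        except sqlite3.IntegrityError as exc:
            raise DuplicateRunError(f"run_id already logged: {record.run_id!r}") from exc
        return record.run_id

    def log_metrics(self, run_id: str, results: Mapping[str, MetricResult]) -> None:
        """Insert one run's battery atomically: either all rows commit or none."""
        row = self._conn.execute(
            "SELECT 1 FROM runs WHERE run_id = ?", (run_id,)
        ).fetchone()
        if row is None:
            raise UnknownRunError(f"unknown run_id: {run_id!r}")
        now = _utcnow()
        try:
            with self._conn:
                for name, res in results.items():
                    missing = res.degenerate and (
                        res.score is None or np.isnan(res.score)
                    )
                    self._conn.execute(
                        "INSERT INTO metric_values (run_id, metric_name, raw_value,"
                        " score, is_missing, computed_at) VALUES (?, ?, ?, ?, ?, ?)",
                        (
                            run_id,
                            res.metric_name,
                            None if np.isnan(res.raw_value) else float(res.raw_value),
                            None if np.isnan(res.score) else float(res.score),
                            int(missing),
                            now,
                        ),
                    )
                self._conn.execute(
                    "UPDATE runs SET status = 'evaluated' WHERE run_id = ?", (run_id,)
                )
        except sqlite3.IntegrityError as exc:
            raise ValueError(f"metric logging failed for {run_id!r}: {exc}") from exc

    def log_battery(self, records: Sequence[RunRecord], table: MetricTable) -> None:
        """Convenience: log runs and their table rows (row order = record order)."""
        for rec, cid in zip(records, table.candidate_ids):
            self.log_run(rec)
            results = {
                m: MetricResult(
                    m,
                    float(table.raws.loc[cid, m]),
                    float(table.scores.loc[cid, m]),
                    "similarity",
                    degenerate=bool(table.degenerate.loc[cid, m]),
                )
                for m in table.scores.columns
            }
            self.log_metrics(rec.run_id, results)

    # -- reads ---------------------------------------------------------
    def count_runs(self, algorithm: Optional[str] = None) -> int:
        if algorithm is None:
            row = self._conn.execute("SELECT COUNT(*) FROM runs").fetchone()
        else:
            row = self._conn.execute(
                "SELECT COUNT(*) FROM runs WHERE algorithm = ?", (algorithm,)
            ).fetchone()
        return int(row[0])

    def get_run(self, run_id: str) -> RunRecord:
        row = self._conn.execute(
            "SELECT run_id, algorithm, parameters_json, image_path, created_at, status"
            " FROM runs WHERE run_id = ?",
            (run_id,),
        ).fetchone()
        if row is None:
            raise UnknownRunError(f"unknown run_id: {run_id!r}")
        return RunRecord(
            run_id=row[0],
            algorithm_name=row[1],
            parameters=json.loads(row[2]),
            image_path=row[3],
            created_at=row[4],
            status=row[5],
        )

    def run_algorithms(self) -> pd.Series:
        """algorithm label per run_id (for grouping/plot coloring)."""
        rows = self._conn.execute(
            "SELECT run_id, algorithm FROM runs ORDER BY run_id"
        ).fetchall()
        return pd.Series({r: a for r, a in rows}, name="algorithm")

    def fetch_table(
        self,
        algorithm: Optional[str] = None,
        parameters: Optional[Dict[str, Any]] = None,
    ) -> MetricTable:
        """Reassemble the n x p metric table, rows in run_id order.

        ``parameters`` filters runs whose assignment matches every given
        key/value pair.  Raises :class:`EmptySelectionError` when nothing
        matches.
        """
        query = (
            "SELECT r.run_id, r.parameters_json, m.metric_name, m.raw_value, m.score,"
            " m.is_missing FROM metric_values m JOIN runs r ON r.run_id = m.run_id"
        )
        args: list = []
        if algorithm is not None:
            query += " WHERE r.algorithm = ?"
            args.append(algorithm)
        rows = self._conn.execute(query + " ORDER BY r.run_id", args).fetchall()
        if parameters:
            rows = [
                row
                for row in rows
                if all(json.loads(row[1]).get(k) == v for k, v in parameters.items())
            ]
        if not rows:
            raise EmptySelectionError("no metric values match the given filter")
        run_ids = sorted({row[0] for row in rows})
        cols = list(METRIC_ORDER)
        scores = pd.DataFrame(np.nan, index=run_ids, columns=cols)
        raws = pd.DataFrame(np.nan, index=run_ids, columns=cols)
        degen = pd.DataFrame(False, index=run_ids, columns=cols)
        for run_id, _params, name, raw, score, missing in rows:
            if name not in scores.columns:
                for df, fill in ((scores, np.nan), (raws, np.nan), (degen, False)):
                    df[name] = fill
            scores.loc[run_id, name] = np.nan if score is None else score
            raws.loc[run_id, name] = np.nan if raw is None else raw
            degen.loc[run_id, name] = bool(missing)
        return MetricTable(scores=scores, raws=raws, degenerate=degen)

    def export_csv(self, out_dir: Union[str, Path]) -> Dict[str, Path]:
        """Dump runs and metric values to CSV files; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        runs = pd.read_sql_query("SELECT * FROM runs ORDER BY run_id", self._conn)
        metrics = pd.read_sql_query(
            "SELECT * FROM metric_values ORDER BY run_id, metric_name", self._conn
        )
        paths = {
            "runs": out_dir / "runs.csv",
            "metric_values": out_dir / "metric_values.csv",
        }
        runs.to_csv(paths["runs"], index=False)
        metrics.to_csv(paths["metric_values"], index=False)
        return paths
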