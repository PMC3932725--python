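-- Relational schema for campaign runs and their metric values.
-- Plain SQL so an embedded engine (sqlite) or a server backend is a drop-in.

CREATE TABLE IF NOT EXISTS runs (
    run_id          TEXT PRIMARY KEY,
    algorithm       TEXT NOT NULL,
    parameters_json TEXT NOT NULL,
    image_path      TEXT,
    created_at      TEXT NOT NULL,
    status          TEXT NOT NULL DEFAULT 'pending'
);

CREATE TABLE IF NOT EXISTS metric_values (
    run_id      TEXT NOT NULL REFERENCES runs(run_id),
    metric_name TEXT NOT NULL,
    raw_value   REAL,
    score       REAL,
    is_missing  INTEGER NOT NULL DEFAULT 0,
    computed_at TEXT NOT NULL,
    PRIMARY KEY (run_id, metric_name)
);
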