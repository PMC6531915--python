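"""Aggregation of experiment artifacts into a single run report."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

ARTIFACT_FILES = {
    "cv_suite": "cv_suite.json",
    "cell_compare": "cell_compare.json",
    "inducibility": "inducibility.json",
    "ecg_smoke": "ecg_smoke.json",
}


def make_report(run_dir: str | Path, seed: int | None = None,
                require: list[str] | None = None) -> dict:
    """Aggregate the JSON artifacts under ``run_dir`` into one report.

    ``require`` names artifacts that must be present (error naming the
    missing file otherwise); by default every artifact found is included
    and at least one must exist.  The report embeds a hash of the
    aggregated content, so re-running on identical artifacts reproduces
    it bit-for-bit (timestamps are not recorded).
    """
    run_dir = Path(run_dir)
    found = {}
    for key, fname in ARTIFACT_FILES.items():
        path = run_dir / fname
        if path.exists():
            found[key] = json.loads(path.read_text())
        elif require and key in require:
            raise FileNotFoundError(f"required artifact missing: {path}")
    if not found:
        raise FileNotFoundError(f"no experiment artifacts found under {run_dir}")

    payload = json.dumps(found, sort_keys=True)
    report = {
        "seed": seed,
        "artifacts": sorted(found),
        "content_hash": hashlib.sha256(payload.encode()).hexdigest(),
        "results": found,
    }
    (run_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
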