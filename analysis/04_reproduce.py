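"""End-to-end reproduction run: model, knockouts, cohort, analysis, checks.

Thin driver over meientry.pipeline.reproduce with the default
configuration; the structured report (peak lags, knockout comparison,
recovery scores, pass/fail checks) lands in results/reproduce/.
"""

import json
import warnings
from pathlib import Path

from meientry import pipeline
from meientry.config import RunConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "reproduce"


def main() -> None:
    cfg = RunConfig(seed=20260924)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = pipeline.reproduce(cfg, output_dir=OUT)
    print(json.dumps(report["model"], indent=2))
    print(json.dumps(report["checks"], indent=2))
    failed = [k for k, ok in report["checks"].items() if not ok]
    if failed:
        print("checks not met:", ", ".join(failed))


if __name__ == "__main__":
    main()
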