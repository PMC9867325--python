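"""Run the whole pipeline through the orchestrator on simulated inputs.

Equivalent to `crisprtrace simulate` followed by `crisprtrace run-all`;
writes arrays, census, hits, STS and PAM outputs plus a JSON report.
"""

import json
import tempfile
from pathlib import Path

from crisprtrace import simulate_host, simulate_phage_db, write_fasta, write_feature_table
from crisprtrace.cli import default_sim_params, run_all
from crisprtrace.config import PipelineConfig

workdir = Path(tempfile.mkdtemp(prefix="crisprtrace_demo_"))
params = default_sim_params(seed=123)
host, truth = simulate_host(params)
targets, _, _ = simulate_phage_db(params, truth.spacers)
write_fasta([host], workdir / "host.fasta")
write_fasta(targets, workdir / "phages.fasta")
write_feature_table(host.features, workdir / "features.tsv", format="tsv")

config = PipelineConfig(
    genome=str(workdir / "host.fasta"),
    targets=str(workdir / "phages.fasta"),
    features=str(workdir / "features.tsv"),
    outdir=str(workdir / "out"),
)
report = run_all(config)
print(json.dumps(report["summary"], indent=1))
print(f"\nstage outputs under {workdir}/out/")

# The summary aggregates each stage: spacer totals from the census, hit
# counts and the per-target fraction, self-target count and the PAM.
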