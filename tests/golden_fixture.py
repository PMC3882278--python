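"""Build the committed golden-report fixture: one small planted study run
end-to-end with a fixed seed.  Used by the determinism test and by
``python tests/golden_fixture.py <out>`` to regenerate the golden file."""

from pathlib import Path

from mirenrich import SimulationConfig, generate_study, run_pipeline, write_study

GOLDEN_CONFIG = SimulationConfig(
    n_genes=300,
    n_samples_pos=12,
    n_samples_neg=12,
    n_mirnas=20,
    n_planted=3,
    regulon_size=25,
    effect_size=1.5,
    algorithm_sensitivity=0.8,
    algorithm_fp_rate=0.1,
    seed=17,
)

PIPELINE_TOML = """\
seed = 17
n_perm = 100
targets = "study/predictions.tsv"
expressed = "study/expressed_mirnas.txt"

[[datasets]]
id = "synthA"
expression = "study/expression.tsv"
labels = "study/labels.tsv"
"""


def run_golden_pipeline(workdir: Path) -> Path:
    """Generate the fixture study under ``workdir`` and run the pipeline.

    Returns the path of the produced ``report.json``.
    """
    workdir = Path(workdir)
    study = generate_study(GOLDEN_CONFIG)
    write_study(study, workdir / "study")
    config_path = workdir / "pipeline.toml"
    config_path.write_text(PIPELINE_TOML)
    run_pipeline(config_path, workdir / "out")
    return workdir / "out" / "report.json"


if __name__ == "__main__":
    import shutil
    import sys
    import tempfile

    out = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("golden_report.json")
    tmp = Path(tempfile.mkdtemp())
    try:
        report = run_golden_pipeline(tmp)
        out.write_bytes(report.read_bytes())
        print(f"wrote {out}")
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
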