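import pathlib

import pytest
from hypothesis import settings, HealthCheck

import phuscreen as ps
from phuscreen.synthetic_data import Group

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

STUDY_SEED = 1


class StudyFixture:
    """Study-like fixture generated once per session: manifest, run specs,
    on-disk inputs, and the full pipeline report at default settings."""

    def __init__(self, root: pathlib.Path, seed: int = STUDY_SEED):
        self.seed = seed
        self.manifest, self.run_normal, self.run_high = ps.build_study_fixture(seed)
        self.mzml_normal = ps.write_mzml(
            ps.generate_run(self.run_normal), root / "normal.mzML")
        self.mzml_high = ps.write_mzml(
            ps.generate_run(self.run_high), root / "high.mzML")
        tables = ps.generate_ident_tables(self.manifest)
        self.ident_normal = root / "ident_normal.tsv"
        self.ident_high = root / "ident_high.tsv"
        tables[Group.NORMAL].to_csv(self.ident_normal, sep="\t", index=False)
        tables[Group.HIGH].to_csv(self.ident_high, sep="\t", index=False)
        self.annotation = root / "annotation.tsv"
        ps.annotation_table(self.manifest).to_csv(self.annotation, sep="\t", index=False)
        self.out_dir = root / "report"
        self.bundle = ps.run_pipeline(
            ps.PipelineConfig(seed=seed),
            self.ident_normal, self.ident_high,
            self.mzml_normal, self.mzml_high,
            annotation=self.annotation, out_dir=self.out_dir,
        )


@pytest.fixture(scope="session")
def study(tmp_path_factory) -> StudyFixture:
    return StudyFixture(tmp_path_factory.mktemp("study"))


def build_and_run(seed: int, root: pathlib.Path) -> StudyFixture:
    """Fresh fixture + pipeline at an arbitrary seed (for multi-seed checks)."""
    d = root / f"seed{seed}"
    d.mkdir()
    return StudyFixture(d, seed=seed)
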