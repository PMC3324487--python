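import numpy as np
import pandas as pd
import pytest

from uripept.annotate import (
    MigrationModel,
    SequenceAnnotation,
    count_basic_residues,
    find_protein_fragments,
    fit_migration_model,
    theoretical_mass,
    validate_assignment,
)
from uripept.core import DataError


class TestCountBasicResidues:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("DSYVGDEAQSK", 1),
            ("IDELYLPK", 1),
            ("GGGG", 0),
            ("KRH", 3),
            ("AkA", 1),  # hydroxylysine counts as lysine
            ("ApGmP", 0),  # hydroxyproline / oxidized Met are not basic
        ],
    )
    def test_counts(self, seq, expected):
        assert count_basic_residues(seq) == expected

    def test_unknown_character_raises(self):
        with pytest.raises(DataError):
            count_basic_residues("AXZ1")

    def test_modification_invariance(self):
        assert count_basic_residues("GPPGK") == count_basic_residues("GppGk")


class TestSequenceAnnotation:
    def test_valid(self):
        ann = SequenceAnnotation("DSYVGDEAQSK", "ACTS_RAT", 53, 63)
        assert ann.n_basic == 1
        assert ann.mass_da == pytest.approx(theoretical_mass("DSYVGDEAQSK"))

    def test_length_mismatch_raises(self):
        with pytest.raises(DataError):
            SequenceAnnotation("GGG", "X", 1, 5)

    def test_start_after_stop_raises(self):
        with pytest.raises(DataError):
            SequenceAnnotation("GG", "X", 5, 4)

    def test_modified_mass_heavier(self):
        assert theoretical_mass("GpG") > theoretical_mass("GPG")


def _training_table(jitter=0.0, seed=0, n_per_stratum=8):
    """Times generated from an exact per-stratum law: t = a_nb + b_nb*log(m),
    with fewer basic residues migrating later (monotone construction)."""
    rng = np.random.default_rng(seed)
    rows = []
    laws = {0: (30.0, 2.0), 1: (24.0, 2.0), 2: (18.0, 2.0)}
    for nb, (a, b) in laws.items():
        for _ in range(n_per_stratum):
            mass = rng.uniform(800, 4000)
            t = a + b * np.log(mass) + rng.normal(0, jitter)
            rows.append({"n_basic": nb, "mass_da": mass, "time_min": t})
    return pd.DataFrame(rows), laws


class TestMigrationModel:
    def test_exact_law_recovered(self):
        table, laws = _training_table()
        model = fit_migration_model(table)
        for nb, (a, b) in laws.items():
            assert model.coef[nb][0] == pytest.approx(a, abs=1e-6)
            assert model.coef[nb][1] == pytest.approx(b, abs=1e-6)

    def test_in_sample_residual_sanity(self):
        table, _ = _training_table(jitter=0.3, seed=1)
        model = fit_migration_model(table)
        row = table.iloc[0]
        pred = model.predict(row["mass_da"], int(row["n_basic"]))
        assert abs(row["time_min"] - pred) < 3 * model.residual_sd + 1e-9

    def test_monotone_in_basic_count(self):
        table, _ = _training_table()
        model = fit_migration_model(table)
        t = [model.predict(2000.0, nb) for nb in (0, 1, 2)]
        assert t[0] > t[1] > t[2]

    def test_small_stratum_excluded_with_warning(self):
        table, _ = _training_table()
        extra = pd.DataFrame(
            [{"n_basic": 5, "mass_da": 1500.0, "time_min": 20.0}] * 2
        )
        with pytest.warns(UserWarning, match="stratum"):
            model = fit_migration_model(pd.concat([table, extra]))
        assert 5 not in model.coef

    def test_too_few_peptides_raises(self):
        table, _ = _training_table(n_per_stratum=2)
        with pytest.raises(DataError):
            fit_migration_model(table.head(5))

    def test_sequence_column_accepted(self):
        table, _ = _training_table()
        seqs = {0: "GGGG", 1: "GGKG", 2: "KGKG"}
        table = table.assign(sequence=[seqs[nb] for nb in table["n_basic"]])
        model = fit_migration_model(table.drop(columns="n_basic"))
        assert set(model.coef) == {0, 1, 2}


class TestValidateAssignment:
    @pytest.fixture()
    def model(self):
        table, _ = _training_table()
        return fit_migration_model(table)

    def _candidate(self, model, ppm_off=0.0, time_off=0.0):
        ann = SequenceAnnotation("DSYVGDEAQSK", "ACTS_RAT", 53, 63)
        mass = ann.mass_da * (1 + ppm_off * 1e-6)
        time = model.predict(ann.mass_da, ann.n_basic) + time_off
        return ann, mass, time

    def test_inside_all_gates_accepts(self, model):
        ann, mass, time = self._candidate(model, ppm_off=30.0, time_off=1.0)
        ok, reasons = validate_assignment(ann, mass, time, model, both_engines=True)
        assert ok and reasons == []

    def test_mass_gate(self, model):
        ann, mass, time = self._candidate(model, ppm_off=60.0)
        ok, reasons = validate_assignment(ann, mass, time, model)
        assert not ok and "mass" in reasons

    def test_migration_gate(self, model):
        ann, mass, time = self._candidate(model, time_off=2.5)
        ok, reasons = validate_assignment(ann, mass, time, model)
        assert not ok and "migration" in reasons

    def test_engine_agreement_gate(self, model):
        ann, mass, time = self._candidate(model)
        ok, reasons = validate_assignment(ann, mass, time, model, both_engines=False)
        assert not ok and "engine_agreement" in reasons

    def test_monotone_in_tolerances(self, model):
        # tightening either tolerance never accepts a rejected candidate
        rng = np.random.default_rng(4)
        for _ in range(30):
            ann, mass, time = self._candidate(
                model, ppm_off=rng.uniform(-80, 80), time_off=rng.uniform(-3, 3)
            )
            loose, _ = validate_assignment(ann, mass, time, model,
                                           ppm_tol=50.0, time_tol=2.0)
            tight, _ = validate_assignment(ann, mass, time, model,
                                           ppm_tol=25.0, time_tol=1.0)
            assert loose or not tight


class TestFindProteinFragments:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        # 5 + 16 + 11 planted fragments of three proteins + 20 other peptides
        proteins = ["clusterin"] * 5 + ["osteopontin"] * 16 + ["albumin"] * 11
        n = len(proteins) + 20
        ann = pd.DataFrame({
            "peptide_id": np.arange(len(proteins)),
            "protein": proteins,
        })
        case_cols = {f"c{j}": np.exp(rng.normal(5, 1, n)) for j in range(10)}
        ctrl_cols = {f"k{j}": np.exp(rng.normal(5, 1, n)) for j in range(10)}
        matrix = pd.DataFrame({**case_cols, **ctrl_cols},
                              index=pd.RangeIndex(n, name="peptide_id"))
        # plant a strong differential signal in fragments 0 and 6
        for j in range(10):
            matrix.loc[0, f"c{j}"] *= np.exp(4.0)
            matrix.loc[6, f"c{j}"] *= np.exp(4.0)
        case = list(case_cols)
        ctrl = list(ctrl_cols)
        return ann, matrix, case, ctrl

    def test_exact_fragment_counts_selected(self):
        ann, matrix, case, ctrl = self._setup()
        out = find_protein_fragments(
            ann, matrix, ["clusterin", "osteopontin", "albumin"], case, ctrl
        )
        assert len(out) == 32
        assert out["protein"].value_counts().to_dict() == {
            "osteopontin": 16, "albumin": 11, "clusterin": 5
        }

    def test_unknown_protein_empty_with_warning(self):
        ann, matrix, case, ctrl = self._setup()
        with pytest.warns(UserWarning, match="kim-1"):
            out = find_protein_fragments(ann, matrix, ["kim-1"], case, ctrl)
        assert out.empty

    def test_planted_differential_recovered(self):
        ann, matrix, case, ctrl = self._setup()
        out = find_protein_fragments(
            ann, matrix, ["clusterin", "osteopontin", "albumin"], case, ctrl
        )
        assert bool(out.loc[0, "significant"])
        assert bool(out.loc[6, "significant"])
        # null fragments mostly non-significant under BH
        null_ids = [i for i in out.index if i not in (0, 6)]
        assert out.loc[null_ids, "significant"].sum() <= 2
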