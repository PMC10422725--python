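"""Generator: tooth meshes, resorption with measured truth, cohorts."""

import numpy as np
import pandas as pd
import pytest

from rootmorph.mesh_core import ValidationError, mesh_volume
from rootmorph.registration import landmark_align, icp_register
from rootmorph.root_analysis import build_radicular_template, root_length
from rootmorph.synthetic_data import (
    DEFAULT_EFFECTS,
    CohortSpec,
    ResorptionSpec,
    ToothTemplateSpec,
    apply_resorption,
    default_lacuna_sites,
    draw_tooth_effects,
    generate_cohort,
    generate_tooth,
    perturb_frame,
)


class TestGenerateTooth:
    def test_p1_cusp_apex_distance_matches_spec(self, p1_tooth):
        mesh, lm = p1_tooth
        spec_len = ToothTemplateSpec.for_class("P1").root_lengths["P1"]
        assert root_length(lm, mesh, "P1") == pytest.approx(spec_len, abs=0.7)
        d = np.linalg.norm(lm["cusp_buccal"] - lm["apex_P1"])
        assert d == pytest.approx(spec_len, abs=1e-6)

    def test_m1_three_roots_watertight(self, m1_tooth):
        mesh, lm = m1_tooth
        assert mesh.is_watertight()
        assert mesh_volume(mesh) > 0
        assert {"apex_M1m", "apex_M1d", "apex_M1p"} <= set(lm.points)

    def test_lower_molar_has_two_roots(self):
        mesh, lm = generate_tooth(ToothTemplateSpec.for_class("M1", arch="lower"), seed=0)
        assert lm.roots == ("M1m", "M1d")
        assert mesh.is_watertight()

    def test_deterministic(self):
        spec = ToothTemplateSpec.for_class("P2")
        a, _ = generate_tooth(spec, seed=3)
        b, _ = generate_tooth(spec, seed=3)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_root_volume_calibration(self, m1_tooth):
        # below-CEJ volume ends up near the per-class target (the CEJ
        # plane sits slightly off the calibration plane, hence the slack)
        mesh, lm = m1_tooth
        template, _ = build_radicular_template(mesh, lm)
        assert mesh_volume(template) == pytest.approx(315.0, rel=0.12)


class TestApplyResorption:
    def test_truncation_recovers_length_change(self, p1_tooth):
        mesh, lm = p1_tooth
        t1, truth = apply_resorption(
            mesh, lm, ResorptionSpec(apical_truncation={"P1": 0.5}), seed=0
        )
        assert truth.true_length_change["P1"] == pytest.approx(0.5, abs=0.15)
        assert t1.is_watertight()

    def test_noop_spec_changes_nothing(self, p1_tooth):
        mesh, lm = p1_tooth
        t1, truth = apply_resorption(mesh, lm, ResorptionSpec(), seed=0)
        assert truth.true_volume_loss == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(t1.vertices, mesh.vertices)

    def test_volume_target_hit_within_5pct(self, p1_tooth):
        mesh, lm = p1_tooth
        rng = np.random.default_rng(1)
        spec = ResorptionSpec(
            lacuna_sites=default_lacuna_sites(mesh, lm, rng),
            target_volume_loss=5.0,
        )
        _, truth = apply_resorption(mesh, lm, spec, seed=1)
        assert truth.true_volume_loss == pytest.approx(5.0, rel=0.05)

    def test_truth_matches_template_cut(self, resorbed_m1):
        """Declared volume loss equals the below-CEJ mesh measurement."""
        from rootmorph.mesh_core import cut_mesh

        t0, lm, t1, truth = resorbed_m1
        _, plane = build_radicular_template(t0, lm)
        v0 = mesh_volume(cut_mesh(t0, plane, keep="below"))
        v1 = mesh_volume(cut_mesh(t1, plane, keep="below"))
        assert truth.true_volume_loss == pytest.approx(v0 - v1, rel=5e-3, abs=1e-6)

    def test_excessive_truncation_rejected(self, p1_tooth):
        mesh, lm = p1_tooth
        with pytest.raises(ValidationError):
            apply_resorption(
                mesh, lm, ResorptionSpec(apical_truncation={"P1": 30.0}), seed=0
            )

    def test_lacunae_sit_on_buccal_apical_surface(self, m1_tooth):
        mesh, lm = m1_tooth
        sites = default_lacuna_sites(mesh, lm, np.random.default_rng(0))
        assert len(sites) == 9
        cej_z = float((lm["CEJB"][2] + lm["CEJL"][2]) / 2)
        for point, radius, depth in sites:
            assert point[2] < cej_z - 2.0  # well below the CEJ
            assert radius > 0 and depth > 0


class TestPerturbFrame:
    def test_zero_bounds_identity(self, p1_tooth):
        mesh, lm = p1_tooth
        moved, lm2, t = perturb_frame(mesh, lm, 0.0, 0.0, seed=0)
        assert t.rotation_angle_deg() < 1e-9
        assert np.allclose(moved.vertices, mesh.vertices)

    def test_rigidity(self, p1_tooth):
        mesh, lm = p1_tooth
        moved, lm2, t = perturb_frame(mesh, lm, 10.0, 5.0, seed=1)
        d0 = np.linalg.norm(lm["cusp_buccal"] - lm["apex_P1"])
        d1 = np.linalg.norm(lm2["cusp_buccal"] - lm2["apex_P1"])
        assert d1 == pytest.approx(d0, rel=1e-12)

    def test_registration_recovers_inverse(self, p1_tooth):
        mesh, lm = p1_tooth
        moved, lm2, t = perturb_frame(mesh, lm, 20.0, 8.0, seed=2)
        init = landmark_align(lm2.registration_points(), lm.registration_points())
        est, report = icp_register(moved, mesh, init=init)
        rms = np.sqrt(np.mean(np.sum((est.apply(moved.vertices) - mesh.vertices) ** 2, axis=1)))
        assert rms < 1e-3


class TestEffectDraws:
    @pytest.mark.parametrize("group", ["TB", "BB"])
    def test_upper_draw_distributions_match_config(self, group):
        """Sample mean/SD of the simulated effects track the configured tables."""
        # calibration is checked on the raw draws; the truncation at zero
        # applied to test-arch teeth is covered separately below
        eff = DEFAULT_EFFECTS[group]["upper"]
        n = 2000
        rng = np.random.default_rng(123)
        dvs, m1p = [], []
        for _ in range(n):
            dv, trunc = draw_tooth_effects(
                eff, "M1", ("M1m", "M1d", "M1p"), rng, truncate_at_zero=False
            )
            dvs.append(dv)
            m1p.append(trunc["M1p"])
        mu, sd = eff["delta_v"]["M1"]
        assert np.mean(dvs) == pytest.approx(mu, rel=0.05)
        assert np.std(dvs, ddof=1) == pytest.approx(sd, rel=0.05)
        mu_l, sd_l = eff["delta_length"]["M1p"]
        assert np.mean(m1p) == pytest.approx(mu_l, rel=0.05)
        assert np.std(m1p, ddof=1) == pytest.approx(sd_l, rel=0.05)

    def test_upper_draws_truncated_at_zero(self):
        eff = DEFAULT_EFFECTS["BB"]["upper"]
        rng = np.random.default_rng(0)
        draws = [draw_tooth_effects(eff, "P1", ("P1",), rng)[0] for _ in range(500)]
        assert min(draws) >= 0.0

    def test_control_draws_keep_sign(self):
        eff = DEFAULT_EFFECTS["TB"]["lower"]
        rng = np.random.default_rng(0)
        draws = [
            draw_tooth_effects(eff, "P1", ("P1",), rng, truncate_at_zero=False)[0]
            for _ in range(200)
        ]
        assert min(draws) < 0 < max(draws)

    def test_volume_length_correlation_positive(self):
        eff = DEFAULT_EFFECTS["TB"]["upper"]
        rng = np.random.default_rng(7)
        pairs = [draw_tooth_effects(eff, "P1", ("P1",), rng, corr=0.5) for _ in range(2000)]
        dv = np.array([p[0] for p in pairs])
        dl = np.array([p[1]["P1"] for p in pairs])
        r = np.corrcoef(dv, dl)[0, 1]
        assert 0.15 < r < 0.55


@pytest.fixture(scope="module")
def small_cohort(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(n_per_group=2, seed=5, tooth_classes=("P1", "M1"))
    manifest = generate_cohort(spec, out)
    return out, spec, manifest


class TestGenerateCohort:
    def test_bookkeeping(self, small_cohort):
        out, spec, manifest = small_cohort
        # 2 groups x 2 patients x 2 arches x 2 classes x 2 sides
        assert len(manifest) == 2 * 2 * 2 * 2 * 2
        stl = list(out.rglob("*.stl"))
        assert len(stl) == 2 * len(manifest)
        for _, row in manifest.iterrows():
            assert (out / row["t0_file"]).exists()
            assert (out / row["t1_file"]).exists()

    def test_truth_files_consistent(self, small_cohort):
        out, spec, manifest = small_cohort
        lengths = pd.read_csv(out / "length_truth.csv")
        upper_m1 = lengths[(lengths.arch == "upper") & (lengths.tooth_class == "M1")]
        assert set(upper_m1["root"]) == {"M1m", "M1d", "M1p"}
        lower_m1 = lengths[(lengths.arch == "lower") & (lengths.tooth_class == "M1")]
        assert set(lower_m1["root"]) == {"M1m", "M1d"}

    def test_reproducible_manifest(self, tmp_path):
        spec = CohortSpec(
            n_per_group=2, seed=9, tooth_classes=("P1",), include_control=False
        )
        a = generate_cohort(spec, tmp_path / "a")
        b = generate_cohort(spec, tmp_path / "b")
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == (
            tmp_path / "b" / "manifest.csv"
        ).read_bytes()
        pd.testing.assert_frame_equal(a, b)

    def test_upper_truth_positive_controls_small(self, small_cohort):
        out, spec, manifest = small_cohort
        upper = manifest[manifest.arch == "upper"]
        assert (upper["true_delta_v_mm3"] >= -1e-6).all()
        lower = manifest[manifest.arch == "lower"]
        assert lower["true_delta_v_mm3"].abs().max() < 6.0  # noise scale
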