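"""Growth metrics, flux partitions, ATP provenance, ratios, t helper."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wjdf.flux_analysis import (
    atp_turnover,
    biomarker_report,
    doubling_time,
    glycolysis_partition,
    growth_summary,
    mlr_t_statistic,
    nucleotide_ratios,
    ppp_partition,
    specific_growth_rate_from_counts,
)
from wjdf.simulate import Trajectory, simulate


@pytest.fixture(scope="module")
def p4_trajectory(network, params_p4):
    return simulate(network, params_p4, t_end=72,
                    t_eval=np.linspace(0, 72, 19))


def make_traj(network, fluxes: dict[str, np.ndarray], n=3) -> Trajectory:
    """Trajectory stub with prescribed constant fluxes."""
    time = np.arange(n, dtype=float)
    data = {rid: np.zeros(n) for rid in network.reaction_ids}
    data.update(fluxes)
    flux = pd.DataFrame(data, index=pd.Index(time, name="time"))
    states = pd.DataFrame(
        {c: np.ones(n) for c in ["X", *network.species_ids]},
        index=flux.index,
    )
    return Trajectory(
        time=time,
        states=states,
        fluxes=flux,
        mu=flux[network.growth_reaction.id],
        diagnostics={"network": network},
    )


class TestGrowthArithmetic:
    @pytest.mark.parametrize(
        "x0,xT,t,expected",
        [
            (0.0375, 0.205, 72.0, 2.36e-2),  # P4 culture, printed densities
            (0.0375, 0.1, 72.0, 1.36e-2),  # P9 culture
        ],
    )
    def test_growth_rate_from_printed_densities(self, x0, xT, t, expected):
        mu = specific_growth_rate_from_counts(x0, xT, t)
        assert mu == pytest.approx(expected, rel=5e-3)

    def test_no_growth(self):
        assert specific_growth_rate_from_counts(0.1, 0.1, 24.0) == 0.0

    @pytest.mark.parametrize(
        "mu,expected",
        [(2.36e-2, 29.4), (1.36e-2, 51.0), (np.log(2), 1.0)],
    )
    def test_doubling_time(self, mu, expected):
        assert doubling_time(mu) == pytest.approx(expected, rel=5e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            specific_growth_rate_from_counts(0.0, 0.1, 24.0)
        with pytest.raises(ValueError):
            doubling_time(0.0)

    @given(x0=st.floats(1e-3, 10), t=st.floats(1.0, 200))
    def test_doubling_roundtrip(self, x0, t):
        # growing from x0 to 2*x0 over T has doubling time exactly T
        mu = specific_growth_rate_from_counts(x0, 2 * x0, t)
        assert doubling_time(mu) == pytest.approx(t, rel=1e-12)

    def test_growth_summary_consistency(self):
        s = growth_summary(0.0375, 0.205, (0.0, 72.0))
        assert s.doubling_time == pytest.approx(np.log(2) / s.mu_avg)


class TestGlycolysisPartition:
    @pytest.mark.parametrize(
        "ldh,pdh,g6pdh,expected",
        [
            (3.0, 1.0, 0.0, (0.75, 0.25, 0.0)),
            (2.0, 2.0, 0.0, (0.5, 0.5, 0.0)),
            # magnitudes of the measured P4 fluxes (recomputed fractions)
            (5.5e-4, 4.4e-4, 1.0e-6, (0.5550, 0.4440, 0.0010)),
        ],
    )
    def test_fraction_values(self, network, ldh, pdh, g6pdh, expected):
        n = 3
        traj = make_traj(network, {
            "LDH": np.full(n, ldh),
            "PDH": np.full(n, pdh),
            "G6PDH": np.full(n, g6pdh),
        })
        part = glycolysis_partition(traj)
        for label, want in zip(("lactate", "tca", "ppp"), expected):
            assert part.fractions[label].iloc[0] == pytest.approx(
                want, abs=5e-5
            )

    def test_zero_denominator_is_missing(self, network):
        traj = make_traj(network, {})
        part = glycolysis_partition(traj)
        assert part.fractions.isna().all().all()


class TestPppPartition:
    def test_single_sink(self, network, params_p4):
        # transketolase carries the entire inflow -> (1, 0, 0)
        traj = make_traj(network, {"G6PDH": np.full(3, 1e-6),
                                   "TK": np.full(3, 1e-6 / 3)})
        part = ppp_partition(traj)
        row = part.fractions.iloc[0]
        assert row["return_to_glycolysis"] == pytest.approx(1.0)
        assert row["cell_synthesis"] == 0.0
        assert row["nucleotide_synthesis"] == 0.0

    def test_prescribed_split(self, network):
        # sinks carrying 55/40/5 percent of the inflow (R5P-weighted)
        g = network.growth_reaction
        a_r5p = abs(float(g.stoichiometry["R5P"]))
        traj = make_traj(network, {
            "G6PDH": np.full(3, 1.0),
            "TK": np.full(3, 0.55 / 3),
            g.id: np.full(3, 0.40 / a_r5p),
            "PPRibP": np.full(3, 0.03),
            "NAT": np.full(3, 0.02),
        })
        part = ppp_partition(traj)
        row = part.fractions.iloc[0]
        assert row["return_to_glycolysis"] == pytest.approx(0.55)
        assert row["cell_synthesis"] == pytest.approx(0.40)
        assert row["nucleotide_synthesis"] == pytest.approx(0.05)


class TestAtpTurnover:
    def test_only_respiration(self, network):
        traj = make_traj(network, {"resp": np.full(3, 1e-4)})
        total, part = atp_turnover(traj)
        assert np.allclose(total, 2.5e-4)  # 2.5 ATP per NADH
        row = part.fractions.iloc[0]
        assert (row["glycolysis"], row["tca"], row["oxphos"]) == (0, 0, 1)

    def test_glycolysis_matches_oxphos(self, network):
        # PGK+PK ATP output equal to respiration's -> (0.5, 0, 0.5)
        traj = make_traj(network, {
            "PGK": np.full(3, 1e-4),
            "PK": np.full(3, 1.5e-4),
            "resp": np.full(3, 1e-4),
        })
        total, part = atp_turnover(traj)
        row = part.fractions.iloc[0]
        assert row["glycolysis"] == pytest.approx(0.5)
        assert row["tca"] == 0.0
        assert row["oxphos"] == pytest.approx(0.5)

    def test_hand_computed_decomposition(self, network):
        # group production rates 2.2, 0.3, 2.4 (x1e-3): total 4.9e-3 and
        # fractions (0.449, 0.061, 0.490)
        traj = make_traj(network, {
            "PGK": np.full(3, 1.0e-3),
            "PK": np.full(3, 1.2e-3),
            "SCOAS": np.full(3, 0.15e-3),
            "SDH": np.full(3, 0.1e-3),  # 1.5 ATP each -> 0.15e-3
            "resp": np.full(3, 0.96e-3),  # 2.5 ATP each -> 2.4e-3
        })
        total, part = atp_turnover(traj)
        assert total.iloc[0] == pytest.approx(4.9e-3, rel=1e-12)
        row = part.fractions.iloc[0]
        assert row["glycolysis"] == pytest.approx(0.449, abs=5e-4)
        assert row["tca"] == pytest.approx(0.061, abs=5e-4)
        assert row["oxphos"] == pytest.approx(0.490, abs=5e-4)

    def test_total_equals_sum_of_components(self, network, params_p4):
        traj = simulate(network, params_p4, t_end=24,
                        t_eval=np.linspace(0, 24, 7))
        total, part = atp_turnover(traj)
        denom = part.fractions.mul(total, axis=0).sum(axis=1)
        assert np.allclose(denom, total, rtol=1e-12)


class TestNucleotideRatios:
    def test_simple_ratios(self):
        frame = pd.DataFrame(
            {"ATP": [1.0, 13.0, 1e-6], "ADP": [1.0, 1.0, 5e-7],
             "AMP": [0.0, 1.0, 5e-7]}
        )
        out = nucleotide_ratios(frame)
        assert out["atp_adp"].tolist() == pytest.approx([1.0, 13.0, 2.0])
        assert out["amp_atp"].iloc[2] == pytest.approx(0.5)

    def test_zero_denominator_warns_and_propagates_nan(self):
        frame = pd.DataFrame({"ATP": [1.0, 0.0], "ADP": [0.0, 1.0],
                              "AMP": [1.0, 1.0]})
        with pytest.warns(UserWarning):
            out = nucleotide_ratios(frame)
        assert np.isnan(out["atp_adp"].iloc[0])
        assert np.isnan(out["amp_atp"].iloc[1])

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            nucleotide_ratios(pd.DataFrame({"ATP": [1.0], "ADP": [1.0]}))


class TestMlrTStatistic:
    def test_identical_groups(self):
        res = mlr_t_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0

    def test_reference_value_df4(self):
        # two triplicates: df = 4, one-sided 95% reference value 2.132
        res = mlr_t_statistic([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.df == 4
        assert res.critical == pytest.approx(2.132, abs=5e-4)

    def test_matches_direct_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 10.0
        res = mlr_t_statistic(a, b)
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        assert res.t == pytest.approx(expected, rel=1e-12)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            mlr_t_statistic([1.0], [1.0, 2.0])


class TestPartitionNormalization:
    def test_all_partitions_sum_to_one(self, network, p4_trajectory):
        for part in (
            glycolysis_partition(p4_trajectory),
            ppp_partition(p4_trajectory),
            atp_turnover(p4_trajectory)[1],
        ):
            sums = part.fractions.sum(axis=1, skipna=False).to_numpy()
            valid = ~np.isnan(sums)
            assert valid.any()
            assert np.allclose(sums[valid], 1.0, atol=1e-9)


def test_biomarker_report_shape(network, p4_trajectory):
    report = biomarker_report(p4_trajectory, condition="P4")
    assert set(report["condition"]) == {"P4"}
    names = set(report["biomarker"])
    assert {"mu_avg", "doubling_time", "glycolysis_lactate",
            "ppp_return_to_glycolysis", "atp_oxphos", "atp_turnover",
            "atp_adp", "amp_atp"} <= names
    mu = report.loc[report["biomarker"] == "mu_avg", "value"].iloc[0]
    assert 0 < mu < 1
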