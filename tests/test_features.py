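"""Distance, timing bins, feature scalings, balancing and splitting."""

import numpy as np
import pandas as pd
import pytest

from fastlabel.cohort_features import (
    SplitSpec,
    build_features,
    curate_balanced,
    haversine_km,
    split_train_test,
    timing_bin_of,
)


class TestHaversine:
    def test_identity_is_zero(self):
        assert haversine_km(24.16, 120.68, 24.16, 120.68) == 0.0

    def test_one_degree_meridian(self):
        assert haversine_km(0, 0, 1, 0) == pytest.approx(
            np.pi / 180 * 6371.0088, abs=1e-6
        )

    def test_antipodal_limit(self):
        assert haversine_km(0, 0, 0, 180) == pytest.approx(np.pi * 6371.0088, abs=1e-3)

    def test_symmetry(self):
        a = haversine_km(24.1, 120.7, 25.0, 121.5)
        b = haversine_km(25.0, 121.5, 24.1, 120.7)
        assert a == pytest.approx(b)

    def test_triangle_inequality_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            lat = rng.uniform(-89, 89, 3)
            lon = rng.uniform(-179, 179, 3)
            ab = haversine_km(lat[0], lon[0], lat[1], lon[1])
            bc = haversine_km(lat[1], lon[1], lat[2], lon[2])
            ac = haversine_km(lat[0], lon[0], lat[2], lon[2])
            assert ac <= ab + bc + 1e-9

    def test_matches_sklearn_on_random_pairs(self):
        from sklearn.metrics.pairwise import haversine_distances

        rng = np.random.default_rng(1)
        lat, lon = rng.uniform(-80, 80, 10), rng.uniform(-170, 170, 10)
        ours = haversine_km(lat[:5], lon[:5], lat[5:], lon[5:])
        theirs = np.array(
            [
                haversine_distances(
                    np.radians([[lat[i], lon[i]]]), np.radians([[lat[i + 5], lon[i + 5]]])
                )[0, 0]
                * 6371.0088
                for i in range(5)
            ]
        )
        np.testing.assert_allclose(ours, theirs, rtol=1e-9)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            haversine_km(91, 0, 0, 0)
        with pytest.raises(ValueError):
            haversine_km(0, 181, 0, 0)


def test_timing_bins():
    out = timing_bin_of(
        pd.to_datetime(
            ["2010-01-01 10:30", "2010-01-01 13:00", "2010-01-01 18:00",
             "2010-01-01 23:30", "2010-01-01 06:59"]
        )
    )
    assert out.tolist() == [
        "07:00-12:59", "13:00-17:59", "18:00-22:59", "other", "other",
    ]


class TestBuildFeatures:
    def _minimal(self):
        labeled = pd.DataFrame(
            {
                "sample_id": ["S1"],
                "record_id": ["S1"],
                "patient_id": ["P1"],
                "request_date": [pd.Timestamp("2015-01-01")],
                "collection_datetime": [pd.Timestamp("2015-01-29 10:30")],
                "value_mgdl": [110.0],
                "division": ["cardiology"],
                "dm_status": [False],
                "labelable": [True],
                "theoretical_fasting": pd.array([True], dtype="boolean"),
                "prior_year_visits": [8],
                "lipid_same_day": [True],
            }
        )
        patients = pd.DataFrame(
            {
                "patient_id": ["P1"],
                "sex": ["male"],
                "birth_date": [pd.Timestamp("1965-01-29")],
                "home_lat": [24.16],
                "home_lon": [120.68],
                "dm_onset_date": [pd.NaT],
                "hypertension_onset": [pd.Timestamp("2010-01-01")],
                "cad_onset": [pd.NaT],
                "stroke_onset": [pd.Timestamp("2016-01-01")],
                "statin_start": [pd.NaT],
            }
        )
        return labeled, patients

    def test_scalings_are_exact_affine(self):
        labeled, patients = self._minimal()
        f = build_features(labeled, patients, hospital_lat=24.16, hospital_lon=120.68)
        row = f.iloc[0]
        assert row["glucose_per5"] * 5 == 110.0
        assert row["interval_per28"] == 1.0  # 28 days / 28
        assert row["visits_per4"] == 2.0  # 8 / 4
        assert row["age_per5"] * 5 == pytest.approx(50.0, abs=0.01)
        assert row["distance_per10"] == 0.0
        assert row["timing_bin"] == "07:00-12:59"
        assert bool(row["male"])
        assert bool(row["hypertension"])
        assert not bool(row["stroke"])  # onset after sampling
        assert not bool(row["label_nonfasting"])  # fasting sample

    def test_missing_coordinates_leave_distance_missing(self):
        labeled, patients = self._minimal()
        patients.loc[0, "home_lat"] = np.nan
        f = build_features(labeled, patients, hospital_lat=24.16, hospital_lon=120.68)
        assert np.isnan(f["distance_per10"].iloc[0])

    def test_visit_history_window_is_half_open(self):
        labeled, patients = self._minimal()
        day = pd.Timestamp("2015-01-29")
        visits = pd.DataFrame(
            {
                "patient_id": ["P1"] * 4,
                "visit_date": [
                    day,  # sampling day: excluded
                    day - pd.Timedelta(days=1),  # included
                    day - pd.Timedelta(days=365),  # included (window start)
                    day - pd.Timedelta(days=366),  # excluded
                ],
            }
        )
        f = build_features(labeled, patients, visits=visits)
        assert f["visits_per4"].iloc[0] == pytest.approx(2 / 4)

    def test_lipid_orders_same_day_join(self):
        labeled, patients = self._minimal()
        lipid = pd.DataFrame(
            {"patient_id": ["P1"], "collection_date": [pd.Timestamp("2015-01-29")]}
        )
        f = build_features(labeled, patients, lipid_orders=lipid)
        assert bool(f["concomitant_lipid_test"].iloc[0])
        f2 = build_features(
            labeled, patients,
            lipid_orders=lipid.assign(collection_date=pd.Timestamp("2015-01-28")),
        )
        assert not bool(f2["concomitant_lipid_test"].iloc[0])


def _toy_features(n_nonfasting, n_fasting, seed=0):
    n = n_nonfasting + n_fasting
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "patient_id": [f"P{i}" for i in range(n)],
            "label_nonfasting": pd.array(
                [True] * n_nonfasting + [False] * n_fasting, dtype="boolean"
            ),
            "glucose_per5": rng.normal(25, 5, n),
        }
    )


class TestBalancingAndSplit:
    def test_undersamples_to_minority(self):
        b = curate_balanced(_toy_features(600, 400), seed=1)
        y = b["label_nonfasting"].to_numpy(dtype=bool)
        assert y.sum() == 400 and (~y).sum() == 400

    def test_deterministic_given_seed(self):
        a = curate_balanced(_toy_features(600, 400), seed=3)
        b = curate_balanced(_toy_features(600, 400), seed=3)
        assert a["sample_id"].tolist() == b["sample_id"].tolist()

    def test_one_sample_per_patient(self):
        f = _toy_features(30, 30)
        f["patient_id"] = ["P0"] * 30 + [f"P{i}" for i in range(30)]
        b = curate_balanced(f, seed=0)
        assert b["patient_id"].is_unique

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            curate_balanced(_toy_features(10, 0), seed=0)

    def test_split_arithmetic_and_partition(self):
        b = curate_balanced(_toy_features(400, 400), seed=0)
        train, test = split_train_test(b, SplitSpec(0.8, seed=4))
        yt = train["label_nonfasting"].to_numpy(dtype=bool)
        ye = test["label_nonfasting"].to_numpy(dtype=bool)
        assert yt.sum() == 320 and (~yt).sum() == 320
        assert ye.sum() == 80 and (~ye).sum() == 80
        ids = set(train["sample_id"]) | set(test["sample_id"])
        assert ids == set(b["sample_id"])
        assert not (set(train["sample_id"]) & set(test["sample_id"]))

    def test_rounding_goes_toward_train(self):
        b = curate_balanced(_toy_features(7, 7), seed=0)
        train, test = split_train_test(b, SplitSpec(0.8, seed=0))
        # floor(7 * 0.2) = 1 per class to test, remainder to train
        assert len(test) == 2 and len(train) == 12

    def test_too_few_rows_raise(self):
        with pytest.raises(ValueError):
            split_train_test(_toy_features(4, 4), SplitSpec(0.8, seed=0))
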