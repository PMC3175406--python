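"""Diet-space mapping, herbivore/plant source derivation, geometry rules."""

import dataclasses

import numpy as np
import pytest

from paleodiet.records import ChronoGroup, Environment, Geography, IsotopeRecord, Taxon
from paleodiet.sources import (
    COLLAGEN_DIET_OFFSETS,
    DegenerateGeometryError,
    FractionationOffsets,
    GeometryMode,
    MissingMixtureError,
    MissingSourceError,
    MixturePoint,
    SourceName,
    SourceSignature,
    barycentric_coordinates,
    build_geometry,
    diet_space_mixture,
    estimate_plant_source,
    herbivore_source,
    triangle_area,
)
from paleodiet.synthetic import FoodwebParams, generate_foodweb


def _hominid(d13c, d15n, i=0):
    return IsotopeRecord(
        f"h{i}", Taxon.NEANDERTHAL, "S", d13c, d15n,
        ChronoGroup.MOIS3_N, Geography.NORTHWEST, Environment.TUNDRA_STEPPE,
    )


def _herb(taxon, d13c, d15n, i=0, site="S"):
    return IsotopeRecord(
        f"{taxon.value}{i}", taxon, site, d13c, d15n,
        ChronoGroup.FAUNA_MOIS3, Geography.NORTHWEST, Environment.TUNDRA_STEPPE,
    )


class TestDietSpaceMixture:
    @pytest.mark.parametrize(
        "collagen, offsets, expected",
        [
            ([(-19.0, 11.0)], (1.05, 4.0), (-20.05, 7.0)),
            ([(-19.0, 11.0), (-21.0, 9.0)], (1.05, 4.0), (-21.05, 6.0)),
            ([(-19.0, 11.0)], (0.0, 0.0), (-19.0, 11.0)),
        ],
    )
    def test_mean_then_offset(self, collagen, offsets, expected):
        records = [_hominid(c, n, i) for i, (c, n) in enumerate(collagen)]
        off = FractionationOffsets(
            dC_range=(0.0, 2.0), dN_range=(0.0, 5.0),
            dC_point=offsets[0], dN_point=offsets[1],
        )
        mix = diet_space_mixture(records, off)
        assert mix.point == pytest.approx(expected)
        assert mix.n_hominids == len(records)

    def test_no_hominids_raises_named_error(self):
        with pytest.raises(MissingMixtureError, match="whole_hominids"):
            diet_space_mixture([])

    def test_translation_property(self):
        """Adding a constant to all collagen values shifts the mixture equally."""
        records = [_hominid(-19.0, 11.0), _hominid(-20.5, 10.0, 1)]
        base = diet_space_mixture(records)
        shifted = diet_space_mixture(
            [
                dataclasses.replace(r, d13C=r.d13C + 0.7, d15N=r.d15N - 1.2)
                for r in records
            ]
        )
        assert shifted.d13C - base.d13C == pytest.approx(0.7)
        assert shifted.d15N - base.d15N == pytest.approx(-1.2)


class TestHerbivoreSource:
    def test_unweighted_mean_ignores_sample_sizes(self):
        records = (
            [_herb(Taxon.REINDEER, -20.0, 5.0, i) for i in range(5)]
            + [_herb(Taxon.HORSE, -19.0, 5.0, i) for i in range(50)]
            + [_herb(Taxon.BOVID, -18.0, 5.0, i) for i in range(500)]
        )
        src = herbivore_source(records, [Taxon.REINDEER, Taxon.HORSE, Taxon.BOVID])
        assert src.mean_d13C == pytest.approx(-19.0)

    def test_singleton_type_set_returns_that_type(self):
        records = [_herb(Taxon.REINDEER, -19.0 + 0.1 * i, 5.0 + 0.2 * i, i) for i in range(4)]
        src = herbivore_source(records, [Taxon.REINDEER])
        vals_c = [r.d13C for r in records]
        assert src.mean_d13C == pytest.approx(np.mean(vals_c))
        assert src.sd_d13C == pytest.approx(np.std(vals_c, ddof=1))

    def test_dn_shift_in_sd_units(self):
        records = [_herb(Taxon.REINDEER, -19.0, 5.0 + dv, i) for i, dv in enumerate([-0.8, 0.8])]
        base = herbivore_source(records, [Taxon.REINDEER])
        shifted = herbivore_source(records, [Taxon.REINDEER], dn_shift_sd=1.0)
        assert shifted.mean_d15N == pytest.approx(base.mean_d15N + base.sd_d15N)

    def test_missing_type_names_it(self):
        records = [_herb(Taxon.REINDEER, -19.0, 5.0)]
        with pytest.raises(MissingSourceError, match="horse"):
            herbivore_source(records, [Taxon.REINDEER, Taxon.HORSE])

    def test_replication_invariance(self):
        """Duplicating records of one type leaves the source unchanged in mean."""
        records = [
            _herb(Taxon.REINDEER, -19.0, 5.0, 0),
            _herb(Taxon.REINDEER, -18.0, 4.0, 1),
            _herb(Taxon.HORSE, -21.0, 6.0, 0),
        ]
        base = herbivore_source(records, [Taxon.REINDEER, Taxon.HORSE])
        doubled = records + [
            dataclasses.replace(r, specimen_id=r.specimen_id + "x")
            for r in records
            if r.taxon is Taxon.HORSE
        ]
        dup = herbivore_source(doubled, [Taxon.REINDEER, Taxon.HORSE])
        assert dup.mean_d13C == pytest.approx(base.mean_d13C)
        assert dup.mean_d15N == pytest.approx(base.mean_d15N)


class TestPlantSource:
    @pytest.mark.parametrize(
        "offsets, expected",
        [((1.05, 4.0), (-21.05, 1.0)), ((0.8, 3.0), (-20.8, 2.0))],
    )
    def test_subtraction_from_herbivore_source(self, offsets, expected):
        herb = SourceSignature(SourceName.MEAT, -20.0, 0.5, 5.0, 0.7)
        off = FractionationOffsets(
            dC_range=(0.8, 1.3), dN_range=(3.0, 5.0),
            dC_point=offsets[0], dN_point=offsets[1],
        )
        plants = estimate_plant_source(herb, off)
        assert (plants.mean_d13C, plants.mean_d15N) == pytest.approx(expected)
        assert plants.sd_d13C == herb.sd_d13C and plants.sd_d15N == herb.sd_d15N

    def test_derived_plant_d15n_stays_in_plant_compartment(self):
        """Herbivores inside their compartment imply plants within 0..6 per mil."""
        from paleodiet.records import HERBIVORE_TAXA
        for seed in range(100):
            records, _ = generate_foodweb(FoodwebParams(seed=seed, fauna_n_per_site=3))
            herb = herbivore_source(
                [r for r in records if r.taxon in HERBIVORE_TAXA],
                [Taxon.REINDEER, Taxon.HORSE, Taxon.BOVID],
            )
            plants = estimate_plant_source(herb)
            assert 0.0 <= plants.mean_d15N <= 6.0


class TestGeometry:
    FISH = SourceSignature(SourceName.FISH, -20.0, 0.5, 12.0, 1.0)
    MEAT = SourceSignature(SourceName.MEAT, -18.0, 0.5, 8.0, 1.0)
    PLANTS = SourceSignature(SourceName.PLANTS, -21.0, 0.4, 1.5, 0.6)
    MIX = MixturePoint(-20.05, 7.0, n_hominids=3)

    def test_extended_pushes_vertices_outward(self):
        geo = build_geometry(self.FISH, self.MEAT, self.PLANTS, self.MIX, mode="extended")
        # meat mean (-18, 8), SD (0.5, 1.0), mixture (-20.05, 7.0) -> (-17.5, 9.0)
        assert geo.vertices[1] == pytest.approx((-17.5, 9.0))

    def test_average_mode_uses_means(self):
        geo = build_geometry(self.FISH, self.MEAT, self.PLANTS, self.MIX, mode="average")
        assert geo.vertices == tuple(s.mean for s in (self.FISH, self.MEAT, self.PLANTS))

    def test_extended_geometry_widens_the_construction(self):
        """On seeded fixtures the extended triangle has at least the average
        area, keeps an interior mixture interior, and moves every vertex
        coordinate at least as far from the mixture as the average vertex.

        (Full containment of the average triangle is NOT guaranteed by the
        per-axis outward rule: with unequal source SDs the extended edges
        rotate and can cut marginally inside an average vertex.)"""
        rng = np.random.default_rng(11)
        for _ in range(100):
            fish = SourceSignature(SourceName.FISH, -20.5 + rng.normal(0, 0.3), 0.5, 12 + rng.normal(0, 0.5), 1.0)
            meat = SourceSignature(SourceName.MEAT, -18.5 + rng.normal(0, 0.3), 0.5, 6 + rng.normal(0, 0.5), 0.8)
            plants = SourceSignature(SourceName.PLANTS, -22.0 + rng.normal(0, 0.3), 0.5, 1.5 + rng.normal(0, 0.5), 0.8)
            # interior mixture
            p = rng.dirichlet([2, 2, 2]) * 0.7 + 0.1
            mx = p @ np.array([fish.mean, meat.mean, plants.mean])
            mix = MixturePoint(float(mx[0]), float(mx[1]), n_hominids=1)
            avg = build_geometry(fish, meat, plants, mix, mode="average")
            ext = build_geometry(fish, meat, plants, mix, mode="extended")
            assert avg.mixture_inside and ext.mixture_inside
            assert ext.area >= avg.area
            for v_ext, v_avg in zip(ext.vertices, avg.vertices):
                for k in range(2):
                    assert abs(v_ext[k] - mx[k]) >= abs(v_avg[k] - mx[k]) - 1e-12

    def test_area_monotone_in_sd_multiplier(self):
        areas = [
            build_geometry(
                self.FISH, self.MEAT, self.PLANTS, self.MIX,
                mode="extended", sd_multiplier=m,
            ).area
            for m in (0.0, 0.5, 1.0, 2.0)
        ]
        assert areas == sorted(areas)

    def test_collinear_vertices_rejected(self):
        fish = SourceSignature(SourceName.FISH, -20.0, 0.0, 10.0, 0.0)
        meat = SourceSignature(SourceName.MEAT, -20.0, 0.0, 8.0, 0.0)
        plants = SourceSignature(SourceName.PLANTS, -20.0, 0.0, 2.0, 0.0)
        with pytest.raises(DegenerateGeometryError):
            build_geometry(fish, meat, plants, MixturePoint(-20.0, 5.0, 1), mode="average")

    def test_outside_mixture_reported_not_clipped(self):
        mix = MixturePoint(-25.0, 7.0, n_hominids=1)
        geo = build_geometry(self.FISH, self.MEAT, self.PLANTS, mix, mode="average")
        assert not geo.mixture_inside

    def test_source_roles_checked(self):
        geo = build_geometry(self.FISH, self.MEAT, self.PLANTS, self.MIX, mode="average")
        assert geo.roles_ok
        swapped = build_geometry(
            dataclasses.replace(self.FISH, mean_d15N=2.0),
            self.MEAT,
            dataclasses.replace(self.PLANTS, mean_d15N=9.0),
            self.MIX,
            mode="average",
        )
        assert not swapped.roles_ok and swapped.role_notes


def test_offsets_validate_points_inside_ranges():
    with pytest.raises(ValueError):
        FractionationOffsets(dC_point=2.0)
    off = COLLAGEN_DIET_OFFSETS
    assert off.dC_range[0] <= off.dC_point <= off.dC_range[1]
    assert off.dN_range[0] <= off.dN_point <= off.dN_range[1]
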