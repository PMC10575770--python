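import pytest

from famseg.cohort import Diagnosis, Family, Individual, TraitGroup, TraitInstrument

AQ = TraitInstrument("adult-AQ", 20.0, 5.0)

SCORES = {
    TraitGroup.NAP: 38.0,
    TraitGroup.MAP: 31.0,
    TraitGroup.BAP: 27.0,
    TraitGroup.AVERAGE: 20.0,
}


def make_individual(iid, fam="FAM1", dx=Diagnosis.DIAGNOSED, group=TraitGroup.NAP,
                    father=None, mother=None):
    ind = Individual(
        individual_id=iid, family_id=fam, father_id=father, mother_id=mother,
        diagnosis=dx,
    )
    if group is not None:
        ind = ind.with_trait(SCORES[group], AQ)
    return ind


def make_family(specs, fam="FAM1"):
    """specs: iterable of (iid, diagnosis, trait_group_or_None)."""
    members = {
        iid: make_individual(iid, fam, dx, group) for iid, dx, group in specs
    }
    return Family(family_id=fam, members=members)


@pytest.fixture(scope="session")
def study_sim(tmp_path_factory):
    """One study-shaped synthetic cohort plus a full pipeline run, shared."""
    from famseg.pipeline import PipelineConfig, run_all
    from famseg.simulate import simulate_cohort, study_config

    base = tmp_path_factory.mktemp("study_sim")
    res = simulate_cohort(study_config(seed=1234), base / "sim")
    cfg = PipelineConfig.from_mapping(
        {
            "vcf": res.paths["vcf"],
            "ped": res.paths["ped"],
            "traits": res.paths["traits"],
            "norms": res.paths["norms"],
            "annotations": res.paths["annotations"],
            "constraint": res.paths["constraint"],
            "tier_sources": res.paths["tier_sources"],
            "out_dir": base / "out",
        }
    )
    manifest = run_all(cfg)
    return res, cfg, manifest


@pytest.fixture(scope="session")
def replay_run(tmp_path_factory):
    """Pipeline run over the inverse-constructed worked-example bundle."""
    from famseg.pipeline import PipelineConfig, run_all
    from famseg.replay import build_replay_bundle

    base = tmp_path_factory.mktemp("replay")
    paths = build_replay_bundle(base / "bundle")
    cfg = PipelineConfig.from_mapping(
        {
            "vcf": paths["vcf"],
            "ped": paths["ped"],
            "traits": paths["traits"],
            "norms": paths["norms"],
            "annotations": paths["annotations"],
            "constraint": paths["constraint"],
            "tier_sources": paths["tier_sources"],
            "out_dir": base / "out",
        }
    )
    manifest = run_all(cfg)
    return paths, cfg, manifest
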