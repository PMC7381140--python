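"""Regenerate the shipped default parameter table.

Usage: python scripts/generate_default_table.py [out.tsv]

Knob values were calibrated so drug-free PT ~ 12 s, drug-free aPTT ~ 30 s,
the clot criterion corresponds to a ~30% fibrinogen reduction, and the
population endpoint means land on their targets.  Edit a knob and rerun to
produce a new table version.
"""
import sys

from coagsim.drug_effects import DrugActionParams
from coagsim.network import NetworkModel, Reaction, Species
from coagsim.pk import PKParameters

S = Species
def R_mm(cat, sub, prod, kcat, km):
    return Reaction("mm_activation", (sub,), prod, catalyst=cat, kcat=kcat, km=km)
def R_cx(a, b, prod, k):
    return Reaction("complex_formation", (a, b), prod, k=k)
def R_fo(sub, prod, k):
    return Reaction("first_order", (sub,), prod, k=k)

# calibration knobs
P = dict(
    k_tf=0.05,
    kcat_tfviia_x=0.045, km_tfviia_x=240.0,
    kcat_tfviia_ix=0.34, km_tfviia_ix=240.0,
    kcat_xa_v=0.2, km_xa_v=70.0,
    kcat_iia_v=2.0, km_iia_v=140.0,
    kcat_iia_viii=0.9, km_iia_viii=110.0,
    k_tenase=0.01,
    kcat_tenase=6.0, km_tenase=160.0,
    k_prothrombinase=0.04,
    kcat_pthb=30.0, km_pthb=300.0,
    kcat_xa_ii=0.005, km_xa_ii=300.0,
    kcat_ixa_x=0.01, km_ixa_x=160.0,
    kcat_fg=84.0, km_fg=7200.0,
    kcat_iia_xiii=0.1, km_iia_xiii=70.0,
    kcat_xlink=0.02, km_xlink=2000.0,
    kcat_ca_xii=0.05, km_ca_xii=500.0,
    kcat_xiia_xi=0.05, km_xiia_xi=200.0,
    kcat_xia_ix=0.15, km_xia_ix=200.0,
    kcat_iia_pc=0.05, km_iia_pc=60.0,
    k_apcps=0.005,
    kcat_apc_va=0.2, km_apc_va=140.0,
    kcat_apc_viiia=0.2, km_apc_viiia=110.0,
    fg0=3600.0,
    warfarin_ic50=140.0,
    rivaroxaban_ki=7.4,
    vk_km=80.0,
    kdeg_iia=40.0, kdeg_xa=15.0,
    kdeg_vk=0.002, kdeg_vko=0.02,
    k_vkor=2.5e-4, k_vk_use=2.5e-5,
    version="coagsim-default-1.0",
)


def build(**overrides) -> NetworkModel:
    p = dict(P)
    p.update(overrides)
    species = [
        S("TF", "cofactor", 0.0, 0.0),
        S("CA", "cofactor", 0.0, 0.0),
        S("VII", "zymogen", 10.0, 0.139, vk_dependent=True),
        S("TF_VIIa", "complex", 0.0, 1.0),
        S("X", "zymogen", 170.0, 0.017, vk_dependent=True),
        S("Xa", "active", 0.0, p["kdeg_xa"]),
        S("V", "zymogen", 20.0, 0.046),
        S("Va", "active", 0.0, 10.0),
        S("Xa_Va", "complex", 0.0, 10.0),
        S("II", "zymogen", 1400.0, 0.0107, vk_dependent=True),
        S("IIa", "active", 0.0, p["kdeg_iia"]),
        S("Fg", "fibrin-related", p["fg0"], 0.007),
        S("Fbn", "fibrin-related", 0.0, 0.0),
        S("XFbn", "fibrin-related", 0.0, 0.0),
        S("VIII", "zymogen", 0.7, 0.058),
        S("VIIIa", "active", 0.0, 20.0),
        S("IX", "zymogen", 90.0, 0.029, vk_dependent=True),
        S("IXa", "active", 0.0, 2.0),
        S("VIIIa_IXa", "complex", 0.0, 20.0),
        S("XI", "zymogen", 30.0, 0.014),
        S("XIa", "active", 0.0, 3.0),
        S("XII", "zymogen", 375.0, 0.0116),
        S("XIIa", "active", 0.0, 3.0),
        S("XIII", "zymogen", 70.0, 0.0046),
        S("XIIIa", "active", 0.0, 2.0),
        S("PC", "zymogen", 60.0, 0.087, vk_dependent=True),
        S("APC", "active", 0.0, 1.8),
        S("PS", "cofactor", 300.0, 0.0165, vk_dependent=True),
        S("APC_PS", "complex", 0.0, 2.0),
        S("Va_i", "active", 0.0, 1.0),
        S("VIIIa_i", "active", 0.0, 1.0),
        S("VK", "vitamin", 100.0, p["kdeg_vk"]),
        S("VKO", "vitamin", 10.0, p["kdeg_vko"]),
    ]
    reactions = [
        R_cx("TF", "VII", "TF_VIIa", p["k_tf"]),
        R_mm("TF_VIIa", "X", "Xa", p["kcat_tfviia_x"], p["km_tfviia_x"]),
        R_mm("TF_VIIa", "IX", "IXa", p["kcat_tfviia_ix"], p["km_tfviia_ix"]),
        R_mm("Xa", "V", "Va", p["kcat_xa_v"], p["km_xa_v"]),
        R_mm("IIa", "V", "Va", p["kcat_iia_v"], p["km_iia_v"]),
        R_mm("IIa", "VIII", "VIIIa", p["kcat_iia_viii"], p["km_iia_viii"]),
        R_cx("VIIIa", "IXa", "VIIIa_IXa", p["k_tenase"]),
        R_mm("VIIIa_IXa", "X", "Xa", p["kcat_tenase"], p["km_tenase"]),
        R_cx("Xa", "Va", "Xa_Va", p["k_prothrombinase"]),
        R_mm("Xa_Va", "II", "IIa", p["kcat_pthb"], p["km_pthb"]),
        R_mm("Xa", "II", "IIa", p["kcat_xa_ii"], p["km_xa_ii"]),
        R_mm("IXa", "X", "Xa", p["kcat_ixa_x"], p["km_ixa_x"]),
        R_mm("IIa", "Fg", "Fbn", p["kcat_fg"], p["km_fg"]),
        R_mm("IIa", "XIII", "XIIIa", p["kcat_iia_xiii"], p["km_iia_xiii"]),
        R_mm("XIIIa", "Fbn", "XFbn", p["kcat_xlink"], p["km_xlink"]),
        R_mm("CA", "XII", "XIIa", p["kcat_ca_xii"], p["km_ca_xii"]),
        R_mm("XIIa", "XI", "XIa", p["kcat_xiia_xi"], p["km_xiia_xi"]),
        R_mm("XIa", "IX", "IXa", p["kcat_xia_ix"], p["km_xia_ix"]),
        R_mm("IIa", "PC", "APC", p["kcat_iia_pc"], p["km_iia_pc"]),
        R_cx("APC", "PS", "APC_PS", p["k_apcps"]),
        R_mm("APC_PS", "Va", "Va_i", p["kcat_apc_va"], p["km_apc_va"]),
        R_mm("APC_PS", "VIIIa", "VIIIa_i", p["kcat_apc_viiia"], p["km_apc_viiia"]),
        R_fo("VKO", "VK", p["k_vkor"]),
        R_fo("VK", "VKO", p["k_vk_use"]),
    ]
    drug_params = DrugActionParams(
        warfarin_imax=1.0,
        warfarin_ic50=p["warfarin_ic50"],
        rivaroxaban_ki=p["rivaroxaban_ki"],
        vk_normal=100.0,
        vk_km=p["vk_km"],
    )
    pk_defaults = {
        "warfarin": PKParameters("warfarin", cl=0.2, v=10.0, f=0.9, ka=1.0,
                                 mw=308.33),
        "rivaroxaban": PKParameters("rivaroxaban", cl=6.0, v=50.0, f=0.8,
                                    ka=1.0, mw=435.88),
    }
    return NetworkModel(species, reactions, version=p["version"],
                        drug_params=drug_params, pk_defaults=pk_defaults)


if __name__ == "__main__":
    net = build()
    out = sys.argv[1] if len(sys.argv) > 1 else "src/coagsim/data/default_network.tsv"
    net.save(out)
    print(f"wrote {out}: {len(net.species)} species, {len(net.reactions)} reactions")
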