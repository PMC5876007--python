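"""Regenerate src/wjdf/data/default_parameters.csv.

The published parameter table only covers the sensitive subset (32 values);
every other kinetic constant of the packaged WJMSC network carries a
documented order-of-magnitude default chosen so that the default scenario
starts near a flux steady state: Km defaults sit at the substrate's typical
concentration scale (so saturation terms start near one half) and vmax
defaults are matched to the flux each branch is expected to carry.  These
are fixture values, not measured claims.  Run from the repository root:

    python scripts/make_default_parameters.py
"""

from pathlib import Path

import pandas as pd

import wjdf.network as nw

# vmax defaults, mmol/1e6 cells/h (Table 1 reactions excluded).
VMAX = {
    "vmaxPGI": 3.5e-4,
    "vmaxPFK": 1.5e-3,
    "vmaxPGK": 8.0e-4,
    "vmaxPK": 3.0e-3,
    "vmaxG6PDH": 6.0e-6,
    "vmaxTK": 3.7e-7,
    "vmaxNAT": 1.0e-7,
    "vmaxPPRibP": 2.0e-7,
    "vmaxSCOAS": 2.4e-3,
    "vmaxFUMase": 1.4e-3,
    "vmaxMDH": 1.4e-3,
    "vmaxME": 6.0e-5,
    "vmaxPC": 4.0e-5,
    "vmaxiNOS": 5.0e-6,
    "vmaxARG1": 1.0e-5,
    "vmaxARGt": 1.0e-5,
    "vmaxASS": 2.0e-5,
    "vmaxASL": 2.0e-5,
    "vmaxIDO": 6.0e-6,
    "vmaxKOT": 4.0e-6,
    "vmaxAlaTA": 3.0e-4,
    "vmaxSDHH": 4.0e-5,
    "vmaxHISARGTA": 2.0e-5,
    "vmaxGDH": 2.0e-4,
    "vmaxASN": 2.0e-5,
    "vmaxASNt": 2.0e-5,
    "vmaxASPt": 2.0e-5,
    "vmaxGLNt": 2.0e-4,
    "vmaxGLUt": 2.0e-5,
    "vmaxGLYt": 2.0e-5,
    "vmaxALAt": 1.2e-3,
    "vmaxSERt": 4.0e-5,
    "vmaxCK": 1.0e-4,
    "vmaxNHG": 5.0e-8,
    "vmaxATPase": 3.2e-3,
}

# Km defaults: keyed by parameter name; units follow the substrate
# compartment (mM extracellular, mmol/1e6 cells intracellular).
KM = {
    "KmHKATP": 8.0e-6,
    "KmPGIG6P": 3.0e-7,
    "KmPFKF6P": 2.0e-7,
    "KmPFKATP": 2.5e-6,
    "KmPGKGAP": 1.0e-7,
    "KmPGKNAD": 1.0e-7,
    "KmPGKADP": 2.0e-7,
    "KmPKPEP": 1.0e-6,
    "KmPKADP": 2.0e-7,
    "KmLDHNADH": 1.0e-7,
    "KmG6PDHG6P": 3.0e-7,
    "KmG6PDHNADP": 5.0e-7,
    "KmTKR5P": 5.0e-7,
    "KmNATR5P": 5.0e-7,
    "KmNATATP": 2.5e-6,
    "KmPPRibPR5P": 5.0e-7,
    "KmPPRibPGLY": 5.0e-7,
    "KmPPRibPATP": 2.5e-6,
    "KmPDHNAD": 1.0e-6,
    "KmCSOXA": 5.0e-8,
    "KmCITSCIT": 2.0e-7,
    "KmCITSNAD": 1.0e-6,
    "KmAKGDHAKG": 8.6e-8,
    "KmAKGDHNAD": 2.0e-7,
    "KmSCOASSCOA": 1.0e-7,
    "KmSCOASADP": 2.0e-7,
    "KmSDHADP": 2.0e-7,
    "KmFUMaseFUM": 1.5e-7,
    "KmMDHMAL": 3.0e-7,
    "KmMDHNAD": 2.0e-7,
    "KmMEMAL": 3.0e-7,
    "KmMENADP": 5.0e-7,
    "KmPCPYR": 2.0e-7,
    "KmPCATP": 2.5e-6,
    "KmiNOSARG": 3.0e-7,
    "KmiNOSNADPH": 5.0e-7,
    "KmARG1ARG": 3.0e-7,
    "KmARGtEARG": 0.6,
    "KmOCTORN": 2.0e-7,
    "KmASSCTR": 1.0e-7,
    "KmASSASP": 5.0e-7,
    "KmASSATP": 2.5e-6,
    "KmASLASUC": 5.0e-8,
    "KmIDOETRP": 2.0e-2,
    "KmKOTEKYN": 5.0e-2,
    "KmASTAOXA": 1.0e-6,
    "KmASTAGLU": 2.0e-6,
    "KmAlaTAPYR": 2.0e-7,
    "KmAlaTAGLU": 2.0e-6,
    "KmSDHHSER": 5.0e-7,
    "KmHISARGTAEHIS": 0.2,
    "KmHISARGTAARG": 3.0e-7,
    "KmGLNaseGLN": 1.0e-6,
    "KmGDHGLU": 2.0e-6,
    "KmGDHNAD": 2.0e-6,
    "KmASNASN": 2.0e-7,
    "KmASNtEASN": 5.0e-2,
    "KmASPtEASP": 3.0e-2,
    "KmGLNtEGLN": 2.0,
    "KmGLUtGLU": 2.0e-6,
    "KmGLYtEGLY": 0.25,
    "KmALAtALA": 5.0e-7,
    "KmSERtESER": 0.25,
    "KmrespNADH": 2.0e-7,
    "KmrespADP": 1.0e-7,
    "KmAKATP": 2.5e-6,
    "KmAKAMP": 4.0e-6,
    "KmCKPCR": 1.0e-6,
    "KmCKADP": 2.0e-7,
    "KmNHGNAD": 1.0e-6,
    "KmNHGATP": 2.5e-6,
    "KmNADPHoxNADPH": 5.0e-7,
    "KmATPaseATP": 2.5e-6,
    "KmgrowthG6P": 5.0e-8,
    "KmgrowthCIT": 1.0e-7,
    "KmgrowthR5P": 8.0e-8,
    "KmgrowthETRP": 8.0e-3,
    "KmgrowthATP": 8.0e-7,
}


def main() -> None:
    net = nw.build_wjmsc_network()
    # map Km parameter -> substrate compartment for the units column
    km_units = {}
    for r in net.reactions:
        for sid, km in r.rate_law.substrate_terms:
            km_units[km] = net.get_species(sid).units

    table1 = pd.read_csv(Path("src/wjdf/data/table1_parameters.csv"))["name"]
    referenced = set(net.parameter_names())

    rows = []
    for name, value in sorted({**VMAX, **KM}.items()):
        units = "mmol/1e6 cells/h" if name.startswith("vmax") else km_units[name]
        rows.append({"name": name, "units": units, "value": value})
    frame = pd.DataFrame(rows)

    covered = set(frame["name"]) | set(table1)
    missing = sorted(referenced - covered)
    extra = sorted(covered - referenced)
    if missing or extra:
        raise SystemExit(f"parameter audit failed: missing={missing} extra={extra}")

    out = Path("src/wjdf/data/default_parameters.csv")
    frame.to_csv(out, index=False)
    print(f"wrote {out}: {len(frame)} defaults (+{len(table1)} published values)")


if __name__ == "__main__":
    main()
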