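"""Regenerate the packaged molecular FCIDUMP fixtures.

Requires pyscf (not a runtime dependency of nofpair); the fixtures were
produced once with pyscf 2.14.0 and checked in, together with pyscf's
own RHF and FCI energies as independent reference metadata.  The
package never evaluates Gaussian integrals itself.

Run from the repository root:  python scripts/make_fixtures.py
"""

import json
from pathlib import Path

from pyscf import ao2mo, fci, gto, scf

DATA = Path(__file__).resolve().parents[1] / "src" / "nofpair" / "data"

SYSTEMS = {
    "h2_sto3g": dict(atom="H 0 0 0; H 0 0 0.7414", basis="sto-3g"),
    "he_631g": dict(atom="He 0 0 0", basis="6-31g"),
    "lih_sto3g": dict(atom="Li 0 0 0; H 0 0 1.5949", basis="sto-3g"),
}


def write_fcidump(path, h1e, eri4, ecore, norb, nelec, thresh=1e-12):
    lines = [
        f"&FCI NORB={norb},NELEC={nelec},MS2=0,",
        " ORBSYM=" + ",".join(["1"] * norb) + ",",
        " ISYM=1,",
        "&END",
    ]
    for i in range(norb):
        for j in range(i + 1):
            for k in range(i + 1):
                lmax = j if k == i else k
                for l in range(lmax + 1):
                    v = eri4[i, j, k, l]
                    if abs(v) > thresh:
                        lines.append(f"{v:23.16E} {i+1:4d} {j+1:4d} {k+1:4d} {l+1:4d}")
    for i in range(norb):
        for j in range(i + 1):
            if abs(h1e[i, j]) > thresh:
                lines.append(f"{h1e[i, j]:23.16E} {i+1:4d} {j+1:4d}    0    0")
    lines.append(f"{ecore:23.16E}    0    0    0    0")
    Path(path).write_text("\n".join(lines) + "\n")


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    meta = {}
    for name, spec in SYSTEMS.items():
        mol = gto.M(**spec, verbose=0)
        mf = scf.RHF(mol).run(conv_tol=1e-12)
        norb = mf.mo_coeff.shape[1]
        h1e = mf.mo_coeff.T @ mf.get_hcore() @ mf.mo_coeff
        eri4 = ao2mo.restore(1, ao2mo.kernel(mol, mf.mo_coeff), norb)
        ecore = float(mol.energy_nuc())
        write_fcidump(DATA / f"{name}.fcidump", h1e, eri4, ecore, norb, mol.nelectron)
        e_fci, _ = fci.FCI(mf).kernel()
        meta[name] = {
            "source": "pyscf 2.14.0, RHF molecular orbitals",
            "atom": spec["atom"],
            "basis": spec["basis"],
            "n_basis": int(norb),
            "n_electrons": int(mol.nelectron),
            "e_nuc": ecore,
            "e_rhf": float(mf.e_tot),
            "e_fci": float(e_fci),
        }
    (DATA / "fixtures.json").write_text(json.dumps(meta, indent=2) + "\n")
    print(json.dumps(meta, indent=2))


if __name__ == "__main__":
    main()
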