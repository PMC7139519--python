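"""Mechanistic molecular descriptors from quantum-chemistry summary quantities.

Thirteen descriptors per analyte, grouped by the interaction they encode:

* hydrophobicity / solvent effects — solvation energy ``SE`` (implicit-solvent
  minus gas-phase enthalpy-corrected energy, kcal/mol);
* antioxidant (HAT and SPLET first-oxidation-step) parameters — hydroxyl count
  ``n_OH``, minimum O-H bond dissociation enthalpy ``BDE_min``, proton affinity
  ``PA`` and electron transfer enthalpy ``ETE`` (kcal/mol);
* electrostatics — total dipole moment ``M_tot`` (Debye), most negative NBO
  excess charge ``delta_min`` (e), and the frontier-orbital quantities
  ``gap_HOMO_LUMO``, ``IP``, ``EA``, global hardness ``eta``, electronic
  chemical potential ``mu`` and electrophilicity ``omega`` (eV).

IP and EA use the Koopmans approximation (IP = -E_HOMO, EA = -E_LUMO); the
reactivity indices follow eta = (IP - EA)/2, mu = -(IP + EA)/2 and
omega = mu**2 / (2 eta). The raw mean orbital energy (IP + EA)/2 is exposed as
:func:`electronegativity`.

Enthalpy-derived descriptors are carried in kcal/mol and orbital-derived ones
in eV; Hartree inputs are converted on ingestion (``HARTREE_TO_KCAL``,
``HARTREE_TO_EV``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DESCRIPTOR_NAMES",
    "HARTREE_TO_KCAL",
    "HARTREE_TO_EV",
    "ReferenceEnthalpies",
    "QMSpeciesRecord",
    "DescriptorVector",
    "solvation_energy",
    "bond_dissociation_enthalpies",
    "electron_transfer_enthalpy",
    "proton_affinity",
    "koopmans_ip_ea",
    "electronegativity",
    "global_reactivity",
    "compute_descriptors",
    "assemble_descriptors",
    "read_qm_records",
    "write_qm_records",
    "read_descriptors",
    "write_descriptors",
]

HARTREE_TO_KCAL = 627.5095
HARTREE_TO_EV = 27.211386

#: Fixed column order of the descriptor matrix.
DESCRIPTOR_NAMES = (
    "SE",
    "n_OH",
    "BDE_min",
    "PA",
    "ETE",
    "delta_min",
    "M_tot",
    "gap_HOMO_LUMO",
    "IP",
    "EA",
    "eta",
    "mu",
    "omega",
)

# Ideal-gas enthalpy of the hydrogen atom: electronic energy -0.5 Eh plus the
# 5/2 RT translational + pV term at 298.15 K (1.481 kcal/mol).
_H_ATOM_ENTHALPY = -0.5 * HARTREE_TO_KCAL + 1.481


class DescriptorError(ValueError):
    """Invalid input to a descriptor computation."""


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise DescriptorError(f"{name}: non-finite value {v!r}")


@dataclass(frozen=True)
class ReferenceEnthalpies:
    """Reference enthalpies (kcal/mol) closing the HAT/SPLET thermodynamic cycle.

    The proton and electron values are phase-specific literature constants;
    the hydrogen-atom enthalpy defaults to the ideal-gas value in both phases.
    """

    H_hydrogen_radical: float = _H_ATOM_ENTHALPY
    H_proton: float = -250.574
    H_electron: float = -17.816
    phase: str = "smd_water"

    @classmethod
    def smd_water(cls) -> "ReferenceEnthalpies":
        """Implicit (SMD) water reference set."""
        return cls(_H_ATOM_ENTHALPY, -250.574, -17.816, "smd_water")

    @classmethod
    def in_vacuo(cls) -> "ReferenceEnthalpies":
        """Gas-phase reference set."""
        return cls(_H_ATOM_ENTHALPY, 1.481, 0.752, "in_vacuo")

    @property
    def cycle_constant(self) -> float:
        """BDE - (PA + ETE) for any one O-H site; depends only on the references."""
        return self.H_hydrogen_radical - self.H_proton - self.H_electron


@dataclass
class QMSpeciesRecord:
    """Per-analyte raw quantum-chemistry summary quantities.

    Enthalpies in kcal/mol, orbital energies in eV, dipole in Debye,
    NBO charge in elementary charge units.
    """

    analyte_id: str
    H_parent: float
    H_radical_per_site: dict[str, float]
    H_anion_per_site: dict[str, float]
    E_invacuo: float
    E_solvent: float
    E_HOMO: float
    E_LUMO: float
    dipole_total: float
    nbo_min_charge: float
    n_OH: int

    def __post_init__(self) -> None:
        _require_finite(
            f"record {self.analyte_id}",
            self.H_parent,
            self.E_invacuo,
            self.E_solvent,
            self.E_HOMO,
            self.E_LUMO,
            self.dipole_total,
            self.nbo_min_charge,
        )
        _require_finite(
            f"record {self.analyte_id} radical enthalpies",
            *self.H_radical_per_site.values(),
        )
        _require_finite(
            f"record {self.analyte_id} anion enthalpies",
            *self.H_anion_per_site.values(),
        )
        if self.n_OH < 0:
            raise DescriptorError(f"record {self.analyte_id}: n_OH < 0")
        if set(self.H_radical_per_site) != set(self.H_anion_per_site):
            raise DescriptorError(
                f"record {self.analyte_id}: radical and anion site labels differ"
            )
        if self.E_LUMO <= self.E_HOMO:
            warnings.warn(
                f"record {self.analyte_id}: E_LUMO <= E_HOMO "
                "(DFT band-gap caveat); proceeding",
                stacklevel=2,
            )


@dataclass
class DescriptorVector:
    """The 13 mechanistic descriptors for one analyte (fixed order)."""

    SE: float
    n_OH: float
    BDE_min: float
    PA: float
    ETE: float
    delta_min: float
    M_tot: float
    gap_HOMO_LUMO: float
    IP: float
    EA: float
    eta: float
    mu: float
    omega: float
    analyte_id: str = field(default="", compare=False)

    def as_series(self) -> pd.Series:
        return pd.Series(
            [getattr(self, name) for name in DESCRIPTOR_NAMES],
            index=list(DESCRIPTOR_NAMES),
            name=self.analyte_id or None,
        )


def solvation_energy(E_solvent: float, E_invacuo: float) -> float:
    """Solvation energy SE = E(solvent) - E(in vacuo), kcal/mol.

    Negative values indicate favorable solvation.
    """
    _require_finite("solvation_energy", E_solvent, E_invacuo)
    return E_solvent - E_invacuo


def bond_dissociation_enthalpies(
    rec: QMSpeciesRecord, ref: ReferenceEnthalpies
) -> tuple[dict[str, float], float]:
    """Per-site O-H BDE map and its minimum, kcal/mol.

    BDE(site) = H(radical at site) + H(H·) - H(parent). Analytes without
    hydroxyl groups have no defined BDE; ``(dict(), nan)`` is returned.
    """
    if rec.n_OH == 0:
        return {}, float("nan")
    if not rec.H_radical_per_site:
        raise DescriptorError(
            f"record {rec.analyte_id}: n_OH >= 1 but radical enthalpy map is empty"
        )
    per_site = {
        site: h_rad + ref.H_hydrogen_radical - rec.H_parent
        for site, h_rad in rec.H_radical_per_site.items()
    }
    return per_site, min(per_site.values())


def electron_transfer_enthalpy(
    rec: QMSpeciesRecord, ref: ReferenceEnthalpies, site: str
) -> float:
    """ETE(site) = H(radical) + H(e-) - H(anion), kcal/mol (SPLET second step)."""
    if site not in rec.H_radical_per_site or site not in rec.H_anion_per_site:
        raise DescriptorError(f"record {rec.analyte_id}: unknown O-H site {site!r}")
    return (
        rec.H_radical_per_site[site] + ref.H_electron - rec.H_anion_per_site[site]
    )


def proton_affinity(
    rec: QMSpeciesRecord, ref: ReferenceEnthalpies, site: str
) -> float:
    """PA(site) = H(anion) + H(H+) - H(parent), kcal/mol (SPLET first step)."""
    if site not in rec.H_anion_per_site:
        raise DescriptorError(f"record {rec.analyte_id}: unknown O-H site {site!r}")
    return rec.H_anion_per_site[site] + ref.H_proton - rec.H_parent


def koopmans_ip_ea(E_HOMO: float, E_LUMO: float) -> tuple[float, float, float]:
    """(IP, EA, gap) in eV from frontier orbital energies via Koopmans' theorem."""
    _require_finite("koopmans_ip_ea", E_HOMO, E_LUMO)
    if E_LUMO <= E_HOMO:
        warnings.warn(
            "E_LUMO <= E_HOMO: negative orbital gap (band-gap caveat); proceeding",
            stacklevel=2,
        )
    return -E_HOMO, -E_LUMO, E_LUMO - E_HOMO


def electronegativity(IP: float, EA: float) -> float:
    """Absolute (Mulliken) electronegativity (IP + EA)/2, eV."""
    return 0.5 * (IP + EA)


def global_reactivity(IP: float, EA: float) -> tuple[float, float, float]:
    """Global hardness eta, chemical potential mu and electrophilicity omega (eV).

    eta = (IP - EA)/2, mu = -(IP + EA)/2, omega = mu**2 / (2 eta). A degenerate
    hardness (eta == 0) leaves omega undefined (nan).
    """
    _require_finite("global_reactivity", IP, EA)
    eta = 0.5 * (IP - EA)
    mu = -electronegativity(IP, EA)
    omega = mu * mu / (2.0 * eta) if eta != 0.0 else float("nan")
    return eta, mu, omega


def compute_descriptors(
    rec: QMSpeciesRecord,
    ref: ReferenceEnthalpies | None = None,
    site_policy: str = "bde_min",
) -> DescriptorVector:
    """Full descriptor vector for one analyte.

    ``site_policy`` controls which O-H site's ETE and PA are reported:
    ``"bde_min"`` (default) uses the weakest-bond (first-oxidation-step) site;
    ``"min"`` takes each quantity's minimum over all sites.
    """
    if ref is None:
        ref = ReferenceEnthalpies.smd_water()
    if site_policy not in ("bde_min", "min"):
        raise DescriptorError(f"unknown site_policy {site_policy!r}")

    se = solvation_energy(rec.E_solvent, rec.E_invacuo)
    per_site_bde, bde_min = bond_dissociation_enthalpies(rec, ref)
    if per_site_bde:
        if site_policy == "bde_min":
            site = min(per_site_bde, key=lambda s: (per_site_bde[s], s))
            ete = electron_transfer_enthalpy(rec, ref, site)
            pa = proton_affinity(rec, ref, site)
        else:
            ete = min(
                electron_transfer_enthalpy(rec, ref, s) for s in per_site_bde
            )
            pa = min(proton_affinity(rec, ref, s) for s in per_site_bde)
    else:
        ete = pa = float("nan")

    ip, ea, gap = koopmans_ip_ea(rec.E_HOMO, rec.E_LUMO)
    eta, mu, omega = global_reactivity(ip, ea)
    return DescriptorVector(
        SE=se,
        n_OH=float(rec.n_OH),
        BDE_min=bde_min,
        PA=pa,
        ETE=ete,
        delta_min=rec.nbo_min_charge,
        M_tot=rec.dipole_total,
        gap_HOMO_LUMO=gap,
        IP=ip,
        EA=ea,
        eta=eta,
        mu=mu,
        omega=omega,
        analyte_id=rec.analyte_id,
    )


def assemble_descriptors(
    records: list[QMSpeciesRecord],
    ref: ReferenceEnthalpies | None = None,
    site_policy: str = "bde_min",
) -> pd.DataFrame:
    """Descriptor matrix (analytes x 13) with the documented fixed column order.

    Analytes without hydroxyl groups carry NaN in BDE_min/PA/ETE; downstream
    modeling drops such rows when those descriptors are selected.
    """
    ids = [rec.analyte_id for rec in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DescriptorError(f"duplicate analyte ids: {dupes}")
    rows = [compute_descriptors(rec, ref, site_policy).as_series() for rec in records]
    out = pd.DataFrame(rows, index=pd.Index(ids, name="analyte_id"))
    return out[list(DESCRIPTOR_NAMES)]


# ---------------------------------------------------------------------------
# I/O: long-format qm_records.csv and wide descriptors.csv
# ---------------------------------------------------------------------------

_ENERGY_QUANTITIES = {"H", "E"}


def _convert(quantity: str, value: float, unit: str) -> float:
    unit = (unit or "").strip().lower()
    if quantity in _ENERGY_QUANTITIES:
        if unit in ("", "kcal/mol", "kcal_mol", "kcal"):
            return value
        if unit in ("hartree", "ha", "au"):
            return value * HARTREE_TO_KCAL
    elif quantity in ("E_HOMO", "E_LUMO"):
        if unit in ("", "ev"):
            return value
        if unit in ("hartree", "ha", "au"):
            return value * HARTREE_TO_EV
    else:
        return value
    raise DescriptorError(f"unsupported unit {unit!r} for quantity {quantity!r}")


def read_qm_records(path) -> list[QMSpeciesRecord]:
    """Read the long-format ``qm_records.csv`` table.

    Columns: analyte_id, species (neutral|radical|anion), site, phase
    (vacuo|smd), quantity (H|E|E_HOMO|E_LUMO|dipole|nbo_min|n_OH), value, unit.
    """
    df = pd.read_csv(path, dtype={"analyte_id": str, "site": str}, keep_default_na=False)
    required = {"analyte_id", "species", "site", "phase", "quantity", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise DescriptorError(f"qm_records table missing columns: {sorted(missing)}")

    records = []
    for analyte_id, grp in df.groupby("analyte_id", sort=False):
        fields: dict = {
            "analyte_id": str(analyte_id),
            "H_radical_per_site": {},
            "H_anion_per_site": {},
        }
        for row in grp.itertuples(index=False):
            value = _convert(row.quantity, float(row.value), str(row.unit))
            key = (row.species, row.quantity)
            if key == ("neutral", "E"):
                fields["E_invacuo" if row.phase == "vacuo" else "E_solvent"] = value
            elif key == ("neutral", "H"):
                fields["H_parent"] = value
            elif key == ("radical", "H"):
                fields["H_radical_per_site"][str(row.site)] = value
            elif key == ("anion", "H"):
                fields["H_anion_per_site"][str(row.site)] = value
            elif key == ("neutral", "E_HOMO"):
                fields["E_HOMO"] = value
            elif key == ("neutral", "E_LUMO"):
                fields["E_LUMO"] = value
            elif key == ("neutral", "dipole"):
                fields["dipole_total"] = value
            elif key == ("neutral", "nbo_min"):
                fields["nbo_min_charge"] = value
            elif key == ("neutral", "n_OH"):
                fields["n_OH"] = int(round(value))
            else:
                raise DescriptorError(
                    f"analyte {analyte_id}: unrecognized row "
                    f"(species={row.species!r}, quantity={row.quantity!r})"
                )
        try:
            records.append(QMSpeciesRecord(**fields))
        except TypeError as exc:
            raise DescriptorError(f"analyte {analyte_id}: incomplete record ({exc})")
    return records


def write_qm_records(records: list[QMSpeciesRecord], path) -> None:
    """Write records to the long-format ``qm_records.csv`` table."""
    rows = []

    def add(analyte, species, site, phase, quantity, value, unit):
        rows.append(
            dict(
                analyte_id=analyte,
                species=species,
                site=site,
                phase=phase,
                quantity=quantity,
                value=value,
                unit=unit,
            )
        )

    for rec in records:
        a = rec.analyte_id
        add(a, "neutral", "", "vacuo", "E", rec.E_invacuo, "kcal/mol")
        add(a, "neutral", "", "smd", "E", rec.E_solvent, "kcal/mol")
        add(a, "neutral", "", "smd", "H", rec.H_parent, "kcal/mol")
        for site in sorted(rec.H_radical_per_site):
            add(a, "radical", site, "smd", "H", rec.H_radical_per_site[site], "kcal/mol")
            add(a, "anion", site, "smd", "H", rec.H_anion_per_site[site], "kcal/mol")
        add(a, "neutral", "", "smd", "E_HOMO", rec.E_HOMO, "eV")
        add(a, "neutral", "", "smd", "E_LUMO", rec.E_LUMO, "eV")
        add(a, "neutral", "", "smd", "dipole", rec.dipole_total, "Debye")
        add(a, "neutral", "", "smd", "nbo_min", rec.nbo_min_charge, "e")
        add(a, "neutral", "", "smd", "n_OH", rec.n_OH, "count")
    pd.DataFrame(rows).to_csv(path, index=False)


def write_descriptors(matrix: pd.DataFrame, path) -> None:
    """Write ``descriptors.csv`` (analyte_id + 13 fixed-order columns)."""
    matrix[list(DESCRIPTOR_NAMES)].to_csv(path, index=True, float_format="%.10g")


def read_descriptors(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="analyte_id").astype(float)
    df.index = df.index.astype(str)
    missing = set(DESCRIPTOR_NAMES) - set(df.columns)
    if missing:
        raise DescriptorError(f"descriptor table missing columns: {sorted(missing)}")
    return df[list(DESCRIPTOR_NAMES)]
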