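"""NIfTI / HDF5 / CSV persistence for series, truths, k-space and maps."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .phantom import PhantomTruth, WashoutSeries
from .sampling import KSpaceSeries, SamplingMask
from .ventmodels import ParameterMaps, RateDensity

__all__ = [
    "save_series", "load_series",
    "save_truth", "load_truth",
    "save_kspace", "load_kspace",
    "save_maps", "save_density_csv", "render_map_png",
]


def _affine(pixel_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_mm
    return aff


def save_series(series: WashoutSeries, path: str | Path) -> Path:
    """One 3-D NIfTI (third axis = breath) plus a JSON sidecar."""
    path = Path(path)
    data = np.moveaxis(series.frames, 0, -1)   # (ny, nx, n_images)
    nib.save(nib.Nifti1Image(data, _affine(series.pixel_size_mm)), str(path))
    sidecar = {
        "gas": series.gas,
        "order": series.order,
        "pixel_size_mm": series.pixel_size_mm,
        "snr": series.meta.get("snr"),
        "seed": series.meta.get("seed"),
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_series(path: str | Path) -> WashoutSeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.moveaxis(np.asanyarray(img.dataobj), -1, 0)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return WashoutSeries(
        frames=data,
        breath_index=np.arange(len(data)),
        gas=meta.get("gas", "F19"),
        order=meta.get("order", "washout"),
        pixel_size_mm=float(meta.get("pixel_size_mm") or img.header.get_zooms()[0]),
        meta=meta,
    )


def save_truth(truth: PhantomTruth, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        for name in ("lung_mask", "s0_map", "r_map", "rprime_map", "beta_map"):
            fh.create_dataset(name, data=getattr(truth, name))
        fh.attrs["snr"] = truth.snr
        fh.attrs["seed"] = truth.seed
        fh.attrs["gas"] = truth.gas
        fh.attrs["n_images"] = truth.n_images
    return path


def load_truth(path: str | Path) -> PhantomTruth:
    with h5py.File(path, "r") as fh:
        return PhantomTruth(
            lung_mask=fh["lung_mask"][()],
            s0_map=fh["s0_map"][()],
            r_map=fh["r_map"][()],
            rprime_map=fh["rprime_map"][()],
            beta_map=fh["beta_map"][()],
            snr=float(fh.attrs["snr"]),
            n_images=int(fh.attrs["n_images"]),
            seed=int(fh.attrs["seed"]),
            gas=str(fh.attrs["gas"]),
        )


def save_kspace(kspace: KSpaceSeries, path: str | Path,
                mask: SamplingMask | None = None) -> Path:
    """Complex data stored as paired real/imag datasets; masks as uint8."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("real", data=kspace.frames.real)
        fh.create_dataset("imag", data=kspace.frames.imag)
        if kspace.observed is not None:
            fh.create_dataset("observed", data=kspace.observed.astype(np.uint8))
        fh.attrs["pe_axis"] = kspace.pe_axis
        fh.attrs["dc_index"] = kspace.dc_index
        if mask is not None:
            fh.create_dataset("pattern", data=mask.pattern)
            fh.attrs["af"] = mask.af
            fh.attrs["scheme"] = mask.scheme
            fh.attrs["seed"] = mask.seed
    return path


def load_kspace(path: str | Path) -> tuple[KSpaceSeries, SamplingMask | None]:
    with h5py.File(path, "r") as fh:
        frames = fh["real"][()] + 1j * fh["imag"][()]
        observed = fh["observed"][()].astype(bool) if "observed" in fh else None
        ksp = KSpaceSeries(
            frames=frames,
            pe_axis=int(fh.attrs["pe_axis"]),
            dc_index=tuple(int(v) for v in fh.attrs["dc_index"]),
            observed=observed,
        )
        mask = None
        if "pattern" in fh:
            mask = SamplingMask(
                pattern=fh["pattern"][()],
                af=float(fh.attrs["af"]),
                scheme=str(fh.attrs["scheme"]),
                seed=int(fh.attrs["seed"]),
            )
    return ksp, mask


def save_maps(params: ParameterMaps, out_dir: str | Path,
              pixel_mm: float = 40.0 / 64.0) -> Path:
    """Multi-volume NIfTI plus a CSV summary (mean, SD per map)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layers, names = [], []
    for name in ("s0_map", "r_map", "rprime_map", "beta_map", "rsem_map",
                 "fit_residual_map"):
        arr = getattr(params, name)
        if arr is not None:
            layers.append(arr)
            names.append(name)
    stack = np.stack(layers, axis=-1)
    nib.save(nib.Nifti1Image(stack, _affine(pixel_mm)), str(out_dir / "maps.nii.gz"))
    (out_dir / "maps.json").write_text(json.dumps({"volumes": names}, indent=2))
    lines = ["map,mean,sd"]
    m = params.mask
    for name, arr in zip(names, layers):
        vals = arr[m]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            sd = vals.std(ddof=1) if vals.size > 1 else 0.0
            lines.append(f"{name},{vals.mean():.6g},{sd:.6g}")
    (out_dir / "summary.csv").write_text("\n".join(lines) + "\n")
    return out_dir


def render_map_png(map_: np.ndarray, mask: np.ndarray, path: str | Path,
                   title: str = "", vmin: float | None = None,
                   vmax: float | None = None) -> Path:
    """Plain rendering of a parameter map (masked, with a colorbar)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    shown = np.ma.masked_where(~np.asarray(mask, bool), np.asarray(map_, float))
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(shown, vmin=vmin, vmax=vmax, interpolation="nearest")
    ax.set_title(title)
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def save_density_csv(density: RateDensity, path: str | Path) -> Path:
    path = Path(path)
    rows = "\n".join(f"{r:.8g},{p:.8g}"
                     for r, p in zip(density.r_grid, density.p_values))
    path.write_text("r,p\n" + rows + "\n")
    return path
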