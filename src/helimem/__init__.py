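"""helimem: amphipathicity, helicity/orientation metrics and binding-mode
classification for helical membrane-active peptides."""

from importlib.resources import files

from .builder import build_ideal_helix, randomize_segment
from .classify import (
    BindingModeCall,
    ClassifierThresholds,
    LDSignPrediction,
    classify_binding_mode,
    predict_ld_signs,
    surface_footprint,
)
from .config import PipelineConfig, load_config
from .geometry import (
    BilayerModel,
    fit_helix_axis,
    peptide_surface_distance,
    residue_insertion_depths,
    smooth_exponential,
    split_leaflets,
    tilt_angle,
)
from .pdbio import read_structures, write_structures
from .pipeline import AnalysisResult, analyze_trajectory
from .secondary import (
    assign_helix,
    hbond_energy,
    helicity_fraction,
    helicity_trace,
    reconstruct_amide_hydrogen,
)
from .sequences import (
    HydrophobicityScale,
    PeptideSequence,
    amphipathicity_profile,
    get_scale,
    helical_wheel,
    metrics_table,
    net_charge,
    parse_peptide,
    read_fasta,
    segment_metrics,
    window_hydrophobic_moment,
    window_hydrophobicity,
)
from .structures import Frame, Trajectory
from .synth import SyntheticSpec, generate_mode_trajectory, make_bilayer

__version__ = "0.1.0"


def bundled_peptides():
    """The five study peptides shipped with the package (FASTA fixture)."""
    return read_fasta(files("helimem").joinpath("data/acp_peptides.fasta"))
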