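# Molar (decadic) extinction coefficients of human hemoglobin in the NIR window,
# per heme, interpolated from the widely used compiled in-vitro spectra
# (Horecker 1943 / van Assendelft 1970 lineage as tabulated for NIRS work).
# Units: mM^-1 cm^-1. Linear interpolation between rows is adequate at this
# spacing for the 750-860 nm window used by continuous-wave oximeters.
# wavelength_nm	eps_o2hb_mM_cm	eps_hhb_mM_cm
750	0.518	1.4052
755	0.550	1.4775
760	0.586	1.5485
765	0.620	1.4388
770	0.650	1.3119
775	0.680	1.1903
780	0.710	1.0754
785	0.740	1.0316
790	0.774	0.9904
795	0.796	0.8725
800	0.816	0.7617
805	0.840	0.7400
810	0.864	0.7181
815	0.890	0.7055
820	0.916	0.6930
825	0.946	0.6930
830	0.974	0.6930
835	0.998	0.6928
840	1.022	0.6924
845	1.040	0.6921
850	1.058	0.6913
855	1.076	0.6915
860	1.092	0.6917
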