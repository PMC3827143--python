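gene	category	ctrl_mean	ctrl_sd	case_mean	case_sd
GBAS	viewpoint	0.874	0.095	0.431	0.010
ASL	viewpoint	0.033	0.005	0.046	0.004
KCTD7	viewpoint	0.067	0.006	0.061	0.003
HIP1	viewpoint	0.119	0.019	0.048	0.013
POR	viewpoint	0.241	0.064	0.201	0.029
MDH2	viewpoint	9.229	0.321	12.32	0.195
ZNF107	control_viewpoint	20.90	2.717	21.87	1.701
AUTS2	novel_interactor	2.739	0.101	0.680	0.006
WBSCR22	positive_control	0.277	0.031	0.125	0.024
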