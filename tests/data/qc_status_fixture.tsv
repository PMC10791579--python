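case_id	contigs	expected_status
case000		none
case001	TRA:P	orphan_VJ
case002	TRB:P	orphan_VDJ
case003	TRG:P	orphan_VJ
case004	TRD:P	orphan_VDJ
case005	IGH:P:IGHM	orphan_VDJ
case006	IGK:P	orphan_VJ
case007	IGL:P	orphan_VJ
case008	TRA:P TRB:P	single_pair
case009	TRA:P TRG:P	extra_pair
case010	TRA:P TRD:P	single_pair
case011	TRA:P IGH:P:IGHM	ambiguous
case012	TRA:P IGK:P	ambiguous
case013	TRA:P IGL:P	ambiguous
case014	TRB:P TRG:P	single_pair
case015	TRB:P TRD:P	orphan_VDJ
case016	TRB:P IGH:P:IGHM	ambiguous
case017	TRB:P IGK:P	ambiguous
case018	TRB:P IGL:P	ambiguous
case019	TRG:P TRD:P	single_pair
case020	TRG:P IGH:P:IGHM	ambiguous
case021	TRG:P IGK:P	ambiguous
case022	TRG:P IGL:P	ambiguous
case023	TRD:P IGH:P:IGHM	ambiguous
case024	TRD:P IGK:P	ambiguous
case025	TRD:P IGL:P	ambiguous
case026	IGH:P:IGHM IGK:P	single_pair
case027	IGH:P:IGHM IGL:P	single_pair
case028	IGK:P IGL:P	extra_pair
case029	TRA:P TRB:P TRG:P	extra_pair
case030	TRA:P TRB:P TRD:P	single_pair
case031	TRA:P TRB:P IGH:P:IGHM	ambiguous
case032	TRA:P TRB:P IGK:P	ambiguous
case033	TRA:P TRB:P IGL:P	ambiguous
case034	TRA:P TRG:P TRD:P	extra_pair
case035	TRA:P TRG:P IGH:P:IGHM	ambiguous
case036	TRA:P TRG:P IGK:P	ambiguous
case037	TRA:P TRG:P IGL:P	ambiguous
case038	TRA:P TRD:P IGH:P:IGHM	ambiguous
case039	TRA:P TRD:P IGK:P	ambiguous
case040	TRA:P TRD:P IGL:P	ambiguous
case041	TRA:P IGH:P:IGHM IGK:P	ambiguous
case042	TRA:P IGH:P:IGHM IGL:P	ambiguous
case043	TRA:P IGK:P IGL:P	ambiguous
case044	TRB:P TRG:P TRD:P	single_pair
case045	TRB:P TRG:P IGH:P:IGHM	ambiguous
case046	TRB:P TRG:P IGK:P	ambiguous
case047	TRB:P TRG:P IGL:P	ambiguous
case048	TRB:P TRD:P IGH:P:IGHM	ambiguous
case049	TRB:P TRD:P IGK:P	ambiguous
case050	TRB:P TRD:P IGL:P	ambiguous
case051	TRB:P IGH:P:IGHM IGK:P	ambiguous
case052	TRB:P IGH:P:IGHM IGL:P	ambiguous
case053	TRB:P IGK:P IGL:P	ambiguous
case054	TRG:P TRD:P IGH:P:IGHM	ambiguous
case055	TRG:P TRD:P IGK:P	ambiguous
case056	TRG:P TRD:P IGL:P	ambiguous
case057	TRG:P IGH:P:IGHM IGK:P	ambiguous
case058	TRG:P IGH:P:IGHM IGL:P	ambiguous
case059	TRG:P IGK:P IGL:P	ambiguous
case060	TRD:P IGH:P:IGHM IGK:P	ambiguous
case061	TRD:P IGH:P:IGHM IGL:P	ambiguous
case062	TRD:P IGK:P IGL:P	ambiguous
case063	IGH:P:IGHM IGK:P IGL:P	extra_pair
case064	TRA:P TRB:P TRG:P TRD:P	extra_pair
case065	TRA:P TRB:P TRG:P IGH:P:IGHM	ambiguous
case066	TRA:P TRB:P TRG:P IGK:P	ambiguous
case067	TRA:P TRB:P TRG:P IGL:P	ambiguous
case068	TRA:P TRB:P TRD:P IGH:P:IGHM	ambiguous
case069	TRA:P TRB:P TRD:P IGK:P	ambiguous
case070	TRA:P TRB:P TRD:P IGL:P	ambiguous
case071	TRA:P TRB:P IGH:P:IGHM IGK:P	ambiguous
case072	TRA:P TRB:P IGH:P:IGHM IGL:P	ambiguous
case073	TRA:P TRB:P IGK:P IGL:P	ambiguous
case074	TRA:P TRG:P TRD:P IGH:P:IGHM	ambiguous
case075	TRA:P TRG:P TRD:P IGK:P	ambiguous
case076	TRA:P TRG:P TRD:P IGL:P	ambiguous
case077	TRA:P TRG:P IGH:P:IGHM IGK:P	ambiguous
case078	TRA:P TRG:P IGH:P:IGHM IGL:P	ambiguous
case079	TRA:P TRG:P IGK:P IGL:P	ambiguous
case080	TRA:P TRD:P IGH:P:IGHM IGK:P	ambiguous
case081	TRA:P TRD:P IGH:P:IGHM IGL:P	ambiguous
case082	TRA:P TRD:P IGK:P IGL:P	ambiguous
case083	TRA:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case084	TRB:P TRG:P TRD:P IGH:P:IGHM	ambiguous
case085	TRB:P TRG:P TRD:P IGK:P	ambiguous
case086	TRB:P TRG:P TRD:P IGL:P	ambiguous
case087	TRB:P TRG:P IGH:P:IGHM IGK:P	ambiguous
case088	TRB:P TRG:P IGH:P:IGHM IGL:P	ambiguous
case089	TRB:P TRG:P IGK:P IGL:P	ambiguous
case090	TRB:P TRD:P IGH:P:IGHM IGK:P	ambiguous
case091	TRB:P TRD:P IGH:P:IGHM IGL:P	ambiguous
case092	TRB:P TRD:P IGK:P IGL:P	ambiguous
case093	TRB:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case094	TRG:P TRD:P IGH:P:IGHM IGK:P	ambiguous
case095	TRG:P TRD:P IGH:P:IGHM IGL:P	ambiguous
case096	TRG:P TRD:P IGK:P IGL:P	ambiguous
case097	TRG:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case098	TRD:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case099	TRA:P TRB:P TRG:P TRD:P IGH:P:IGHM	ambiguous
case100	TRA:P TRB:P TRG:P TRD:P IGK:P	ambiguous
case101	TRA:P TRB:P TRG:P TRD:P IGL:P	ambiguous
case102	TRA:P TRB:P TRG:P IGH:P:IGHM IGK:P	ambiguous
case103	TRA:P TRB:P TRG:P IGH:P:IGHM IGL:P	ambiguous
case104	TRA:P TRB:P TRG:P IGK:P IGL:P	ambiguous
case105	TRA:P TRB:P TRD:P IGH:P:IGHM IGK:P	ambiguous
case106	TRA:P TRB:P TRD:P IGH:P:IGHM IGL:P	ambiguous
case107	TRA:P TRB:P TRD:P IGK:P IGL:P	ambiguous
case108	TRA:P TRB:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case109	TRA:P TRG:P TRD:P IGH:P:IGHM IGK:P	ambiguous
case110	TRA:P TRG:P TRD:P IGH:P:IGHM IGL:P	ambiguous
case111	TRA:P TRG:P TRD:P IGK:P IGL:P	ambiguous
case112	TRA:P TRG:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case113	TRA:P TRD:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case114	TRB:P TRG:P TRD:P IGH:P:IGHM IGK:P	ambiguous
case115	TRB:P TRG:P TRD:P IGH:P:IGHM IGL:P	ambiguous
case116	TRB:P TRG:P TRD:P IGK:P IGL:P	ambiguous
case117	TRB:P TRG:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case118	TRB:P TRD:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case119	TRG:P TRD:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case120	TRA:P TRB:P TRG:P TRD:P IGH:P:IGHM IGK:P	ambiguous
case121	TRA:P TRB:P TRG:P TRD:P IGH:P:IGHM IGL:P	ambiguous
case122	TRA:P TRB:P TRG:P TRD:P IGK:P IGL:P	ambiguous
case123	TRA:P TRB:P TRG:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case124	TRA:P TRB:P TRD:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case125	TRA:P TRG:P TRD:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case126	TRB:P TRG:P TRD:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case127	TRA:P TRB:P TRG:P TRD:P IGH:P:IGHM IGK:P IGL:P	ambiguous
case128	TRA:N	none
case129	TRA:P TRA:N	orphan_VJ
case130	TRA:P TRA:P	extra_pair
case131	TRA:P TRA:P TRA:P	extra_pair
case132	TRA:P TRA:N TRA:N	orphan_VJ
case133	TRB:N	none
case134	TRB:P TRB:N	orphan_VDJ
case135	TRB:P TRB:P	extra_pair
case136	TRB:P TRB:P TRB:P	extra_pair
case137	TRB:P TRB:N TRB:N	orphan_VDJ
case138	TRG:N	none
case139	TRG:P TRG:N	orphan_VJ
case140	TRG:P TRG:P	extra_pair
case141	TRG:P TRG:P TRG:P	extra_pair
case142	TRG:P TRG:N TRG:N	orphan_VJ
case143	TRD:N	none
case144	TRD:P TRD:N	orphan_VDJ
case145	TRD:P TRD:P	extra_pair
case146	TRD:P TRD:P TRD:P	extra_pair
case147	TRD:P TRD:N TRD:N	orphan_VDJ
case148	IGH:N:IGHM	none
case149	IGH:P:IGHM IGH:N:IGHM	orphan_VDJ
case150	IGH:P:IGHM IGH:P:IGHM	extra_pair
case151	IGH:P:IGHM IGH:P:IGHM IGH:P:IGHM	extra_pair
case152	IGH:P:IGHM IGH:N:IGHM IGH:N:IGHM	orphan_VDJ
case153	IGK:N	none
case154	IGK:P IGK:N	orphan_VJ
case155	IGK:P IGK:P	extra_pair
case156	IGK:P IGK:P IGK:P	extra_pair
case157	IGK:P IGK:N IGK:N	orphan_VJ
case158	IGL:N	none
case159	IGL:P IGL:N	orphan_VJ
case160	IGL:P IGL:P	extra_pair
case161	IGL:P IGL:P IGL:P	extra_pair
case162	IGL:P IGL:N IGL:N	orphan_VJ
case163	IGH:P:IGHM IGH:P:IGHD	orphan_VDJ
case164	IGH:P:IGHM IGH:P:IGHD IGK:P	single_pair
case165	IGH:P:IGHM IGH:P:IGHD IGH:P:IGHG1	extra_pair
case166	IGH:P:IGHM IGH:P:IGHM	extra_pair
case167	IGH:P:IGHM IGH:P:IGHG1	extra_pair
case168	IGH:P:IGHM IGH:N:IGHG1 IGK:P	single_pair
case169	IGH:P:IGHM IGH:P:IGHD IGH:N:IGHG1	extra_pair
case170	TRB:P TRD:P	orphan_VDJ
case171	TRB:P TRD:P TRA:P	single_pair
case172	TRB:P TRB:P TRA:P	extra_pair
case173	TRA:P TRG:P	extra_pair
case174	TRA:P TRG:P TRB:P	extra_pair
case175	IGK:P IGL:P	extra_pair
case176	TRB:P IGH:P:IGHM	ambiguous
case177	TRB:N IGK:P	ambiguous
case178	TRA:N TRB:P	orphan_VDJ
case179	TRB:P TRA:N TRA:N	orphan_VDJ
case180	TRD:P TRD:P TRB:P	extra_pair
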