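dsb_id	gene_id	tc	position_class	exon_class
DSB001	.	false	intergenic	not_applicable
DSB002	.	false	intergenic	not_applicable
DSB003	.	false	intergenic	not_applicable
DSB004	.	false	intergenic	not_applicable
DSB005	.	false	intergenic	not_applicable
DSB006	.	false	intergenic	not_applicable
DSB007	.	false	intergenic	not_applicable
DSB008	.	false	intergenic	not_applicable
DSB009	.	false	intergenic	not_applicable
DSB010	.	false	intergenic	not_applicable
DSB011	.	false	intergenic	not_applicable
DSB012	.	false	intergenic	not_applicable
DSB013	.	false	intergenic	not_applicable
DSB014	.	false	intergenic	not_applicable
DSB015	.	false	intergenic	not_applicable
DSB016	GENE001	true	promoter	not_applicable
DSB016	GENE002	true	five_prime	exonic
DSB017	GENE003	true	promoter	not_applicable
DSB017	GENE004	true	five_prime	exonic
DSB018	GENE005	true	promoter	not_applicable
DSB018	GENE006	true	five_prime	exonic
DSB019	GENE007	true	promoter	not_applicable
DSB019	GENE008	true	five_prime	exonic
DSB020	GENE009	true	promoter	not_applicable
DSB020	GENE010	true	five_prime	exonic
DSB021	GENE011	true	promoter	not_applicable
DSB021	GENE012	true	five_prime	exonic
DSB022	GENE013	true	promoter	not_applicable
DSB022	GENE014	true	five_prime	exonic
DSB023	GENE015	true	promoter	not_applicable
DSB023	GENE016	true	five_prime	exonic
DSB024	GENE017	true	promoter	not_applicable
DSB024	GENE018	true	five_prime	exonic
DSB025	GENE019	true	promoter	not_applicable
DSB025	GENE020	true	five_prime	exonic
DSB026	GENE021	true	promoter	not_applicable
DSB026	GENE022	true	five_prime	exonic
DSB027	GENE023	true	promoter	not_applicable
DSB028	GENE024	true	promoter	not_applicable
DSB029	GENE025	true	promoter	not_applicable
DSB030	GENE026	true	promoter	not_applicable
DSB031	GENE027	true	promoter	not_applicable
DSB032	GENE028	true	promoter	not_applicable
DSB033	GENE029	true	promoter	not_applicable
DSB034	GENE030	true	promoter	not_applicable
DSB035	GENE031	true	promoter	not_applicable
DSB036	GENE032	true	promoter	not_applicable
DSB037	GENE033	true	promoter	not_applicable
DSB038	GENE034	true	promoter	not_applicable
DSB039	GENE035	true	promoter	not_applicable
DSB040	GENE036	true	promoter	not_applicable
DSB041	GENE037	true	promoter	not_applicable
DSB042	GENE038	true	promoter	not_applicable
DSB043	GENE039	true	promoter	not_applicable
DSB044	GENE040	true	promoter	not_applicable
DSB045	GENE041	true	promoter	not_applicable
DSB046	GENE042	true	promoter	not_applicable
DSB047	GENE043	true	five_prime	exonic
DSB048	GENE044	true	five_prime	exonic
DSB049	GENE045	true	five_prime	exonic
DSB050	GENE046	true	five_prime	exonic
DSB051	GENE047	true	five_prime	intronic
DSB052	GENE048	true	five_prime	intronic
DSB053	GENE049	true	five_prime	intronic
DSB054	GENE050	true	five_prime	intronic
DSB055	GENE051	true	five_prime	intronic
DSB056	GENE052	true	five_prime	intronic
DSB057	GENE053	true	five_prime	intronic
DSB058	GENE054	true	five_prime	intronic
DSB059	GENE055	true	five_prime	intronic
DSB060	GENE056	true	five_prime	intronic
DSB061	GENE057	true	five_prime	intronic
DSB062	GENE058	true	five_prime	intronic
DSB063	GENE059	true	five_prime	intronic
DSB064	GENE060	true	five_prime	intronic
DSB065	GENE061	true	five_prime	intronic
DSB066	GENE062	true	five_prime	intronic
DSB067	GENE063	true	five_prime	intronic
DSB068	GENE064	true	five_prime	intronic
DSB069	GENE065	true	five_prime	intronic
DSB070	GENE066	true	five_prime	intronic
DSB071	GENE067	true	five_prime	intronic
DSB072	GENE068	true	gene_body	exonic
DSB073	GENE069	true	gene_body	exonic
DSB074	GENE070	true	gene_body	exonic
DSB075	GENE071	true	gene_body	exonic
DSB076	GENE072	true	gene_body	intronic
DSB077	GENE073	true	gene_body	intronic
DSB078	GENE074	true	gene_body	intronic
DSB079	GENE075	true	gene_body	intronic
DSB080	GENE076	true	gene_body	intronic
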