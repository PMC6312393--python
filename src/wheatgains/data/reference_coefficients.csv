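wheat_type,ols_yield,ols_stars,jp_variance,jp_variance_stars,jp_yield,jp_yield_stars,n_obs,mean_yield_kg_ha,first_release_year,base_yield_kg_ha
winter,160.99,***,0.12,**,163.00,***,4287,2760.2,1992,3123
spring_irrigated,65.13,***,0.02,,64.81,***,8527,6696.4,1994,6561.41
spring_dryland,20.82,,-0.12,,19.79,,2299,3548.5,1994,
facultative,51.90,***,-0.01,,52.57,***,10577,2825,1994,2755.51
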