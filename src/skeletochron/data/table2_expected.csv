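individual,element,mean_difference_mm,sd_mm,n,p_value,ci_half_width_mm,reject
MOR-OST 1648,coracoid,0.59,0.60,3,0.23,1.48,False
MOR-OST 1648,fibula,0.16,0.04,2,0.10,0.33,False
MOR-OST 1648,femur,0.16,0.00,2,0.01,0.03,False
MOR-OST 1648,humerus,0.10,0.08,2,0.34,0.75,False
MOR-OST 1648,radius,0.02,0.11,4,0.77,0.17,False
MOR-OST 1648,tibia,0.07,0.06,3,0.15,0.14,False
MOR-OST 1648,ulna,0.03,0.05,3,0.35,0.11,False
MOR-OST 1649,coracoid,0.21,0.24,3,0.28,0.60,False
MOR-OST 1649,fibula,0.11,0.16,4,0.27,0.25,False
MOR-OST 1649,femur,0.57,0.51,4,0.11,0.81,False
MOR-OST 1649,humerus,0.00,0.18,4,0.99,0.29,False
MOR-OST 1649,scapula,1.38,0.46,2,0.15,4.11,False
MOR-OST 1649,tibia,0.05,0.26,4,0.74,0.42,False
MOR-OST 1649,ulna,0.00,0.15,4,0.99,0.23,False
MOR-OST 1650,fibula,0.14,0.17,5,0.14,0.22,False
MOR-OST 1650,femur,0.36,0.88,5,0.41,1.09,False
MOR-OST 1650,humerus,0.09,0.12,5,0.17,0.15,False
MOR-OST 1650,radius,0.00,0.62,6,1.00,0.58,False
MOR-OST 1650,tibia,0.55,0.30,4,0.04,0.48,True
MOR-OST 1650,ulna,0.27,0.10,5,0.00,0.12,True
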